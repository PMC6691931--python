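# Methods

## The locus-to-gene model

The pipeline assumes the causal path *associated variant → enhancer →
physical chromatin contact → promoter → gene*. Its unit of resolution is the
restriction fragment: CHi-C reports contacts between fragments, not base
pairs, so every genomic annotation (SNPs, chromatin states, TSSs) is lifted
onto the fragment map before filtering. A fragment map must be a partition —
sorted, non-overlapping, contiguous per chromosome — and loading fails
otherwise; this is what makes point-to-fragment assignment a well-defined
binary search.

A locus is an index SNP plus its LD proxies at r² ≥ `r2_threshold`
(default 0.8, the conventional proxy cut). The filter keeps an interaction
when, in the same cell type, the LD-block-side fragment overlaps at least
`min_overlap` bp (default 1, i.e. any overlap) of an enhancer-state segment
and the partner fragment likewise overlaps a promoter-state segment. The
filter is orientation-free — the block fragment may be bait or other end —
because the capture design baited the associated regions and the underlying
biology is symmetric in the call. Genes are extracted by TSS-in-fragment
(the promoter state is a TSS annotation); a gene-body-overlap mode exists
behind `gene_mode: body` for sensitivity analyses and is always a superset.
Finally a gene must be expressed (value ≥ `expression_threshold`) in at
least one configured cell type.

Key parameters, units and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `r2_threshold` | LD proxy inclusion | 0.8 | standard proxy definition |
| `score_threshold` | CHICAGO-style interaction score cut | 5.0 | the conventional CHICAGO significance cut; the upstream caller's score is consumed, not recomputed |
| `expression_threshold` | expression units (e.g. TPM) | 1.0 | the usual "detectably expressed" convention |
| `min_overlap` | bp of fragment×segment overlap for a state call | 1 | any overlap counts; fragments (~4 kb) are much longer than many state segments |
| `enhancer_states` | ChromHMM 15-state enhancer set | 6_EnhG, 7_Enh, 12_EnhBiv | the Roadmap enhancer mnemonics |
| `promoter_states` | ChromHMM 15-state promoter set | 1_TssA, 2_TssAFlnk, 10_TssBiv | active/flanking/bivalent TSS states |
| `alpha` | BH FDR level for pathway significance | 0.05 | conventional |

Both state sets are configuration keys because "enhancer states" and
"promoter states" are model-dependent choices; unknown state labels are
warned about and treated as neither.

## GWAS comparison

Loci are categorised by whether the reported GWAS gene is recovered and by
how many candidates accompany it (`no_chic_genes`, `0`, `1`, `2-5`, `6+`).
Comparison is symbol-based and case-insensitive with no alias expansion (an
alias table can be applied upstream); a locus reported with several
comma-separated genes counts as recovered if any matches. Loci lacking a
reported gene are excluded from the counts rather than forced into a
category. The counts partition the categorisable loci by construction.

## Drugs and indication matching

The drug stage is a join on normalised gene symbols followed by text
matching. "Currently used" is defined literally as a disease name variant
occurring case-insensitively in the indication text (`substring` mode). That
rule cannot see negated mentions ("not indicated for...") and misses
word-insertion variants; a `token_subset` mode treats a term as matched when
all its word tokens occur anywhere in the indication, trading precision for
recall. Drugs are counted once per disease regardless of how many candidate
genes they hit; gene counts and drug counts are reported separately. No
approval-group filter is applied by default; `groups: [approved]` restricts
to approved drugs.

## Enrichment and refinement

For each disease the candidate list is tested against every pathway with the
one-sided hypergeometric tail P(X ≥ k) (equivalently Fisher's exact test for
over-representation), where the 2×2 margins are taken after intersecting
both the query and the pathway with the universe. The default universe is
the union of all genes in the supplied GMT — the knowledge-base convention —
with `annotated` (all genes in the annotation) and `expressed` universes as
options, since the universe choice is a genuine analytical degree of
freedom. P-values are BH-adjusted per disease across the pathway collection;
a pathway is significant at adjusted p ≤ α. The test is one-sided by design:
depletion is not of interest here.

Cell-type specificity is assessed by rerunning the enrichment on the
candidates supported in each single cell type: a pooled-significant pathway
is labelled `Both` if significant in both single-cell-type runs, with the
cell type's name if in exactly one, and `Pooled-only` otherwise. Each
pathway's SNP-association count is the number of distinct index SNPs
contributing at least one overlap gene (a gene claimed by several loci
contributes all of them).

Refinement intersects the candidates with the union of significant pathways
(so refined ⊆ candidates always), and the expansion takes the full gene sets
of significant pathways as the enlarged drug-target search space; both are
mapped to drugs by the same join/classification operations.

## The synthetic study

The generator tiles a 3×3 Mb toy genome into ~4 kb fragments (uniform
2–6 kb, matching the few-kb scale of a real restriction digest) and plants
66 loci (22 per disease) drawn from six archetypes: fully wired positives
(35%), positives whose single candidate is the reported gene (15%), and
12.5% each of four failure modes — no enhancer state, no promoter state,
gene unexpressed, interaction below threshold. Positive loci cycle through
sub-kinds that vary the candidate count and reported-gene membership so every
comparison category is populated; some promoter fragments carry two TSSs to
exercise multi-gene extraction. Proxies are placed within ±50 kb with r²
uniform on [0.5, 1.0] so the 0.8 cut bites on both sides; locus windows are
separated by ≥60 kb, beyond proxy reach, which is what makes the planted
expectations exact rather than approximate. Every other candidate gene is
made a drug target; roughly a third of the drugs carry the disease name in
their indication; decoy drugs target non-candidate genes. One pathway per
disease is stuffed with ~60% of that disease's candidates plus background
filler; ten background pathways draw only from a disjoint background gene
pool, so exactly the planted pathways can reach significance.

What the fixture does **not** emulate: realistic contact-frequency decay
with distance, realistic LD structure (r² is independent of distance),
overlapping or genome-covering chromatin-state segmentation, cell-type
specific wiring (states and interactions are planted in both cell types, so
planted pathways are labelled `Both`), gene-name aliases, and negated or
ambiguous indication text. Passing tests therefore demonstrate the
correctness of the filtering, counting and testing logic under known truth —
not the biological validity of any particular threshold on real data.

An independent brute-force checker in the test suite (plain linear scans
over the written files, sharing no code with the pipeline) replays the
filter and must agree both with the planted truth and with the pipeline.

## Numerical choices

- Fisher p-values use the survival function of the hypergeometric
  distribution (`P(X ≥ k)` via `sf(k-1)`), clamped to [0, 1]; tests verify
  agreement with exact rational enumeration to 1e-10 for all margins ≤ 30.
- BH adjustment is the standard step-up with monotonisation and cap at 1;
  significance is `p_adj ≤ α`. An independent step-up implementation is the
  oracle in tests.
- Symmetric interaction records ((A,B) vs (B,A)) are deduplicated at load to
  canonical order (lower coordinate first), keeping the higher score on
  conflict.
- Gene symbols are trimmed and upper-cased at every boundary.
- SNP tables are 1-based (dbSNP convention) and converted to 0-based
  half-open internally; all BED I/O is 0-based half-open.
- All writers sort deterministically, so identical (config, seed) produce
  byte-identical files; the pipeline writes a manifest with the config hash
  and SHA-256 of every input.
- Problem sizes in tests and the acceptance script (66 loci, ~2,200
  fragments, margins ≤ 30 for the enumeration grid, 1,000 random p-vectors)
  were chosen so the full suite completes in seconds while still exercising
  every code path and boundary.

## Known limitations

- The pipeline consumes pre-called interaction scores; it neither implements
  nor approximates the upstream statistical caller.
- The indication-matching rule is intentionally literal; clinical nuance
  (contraindication, withdrawal, combination therapy) is out of scope.
- Reported-gene comparison has no alias resolution; symbol drift between
  annotation generations must be handled upstream.
- Per-disease enrichment treats diseases independently; cross-disease
  pooling is not supported.
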
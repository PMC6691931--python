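"""The core locus-to-gene filter.

Starting from GWAS index SNPs and their LD proxies, the filter keeps
CHi-C interactions whose SNP-side restriction fragment overlaps enhancer
chromatin states and whose other end overlaps promoter states in the same
cell type, extracts genes whose TSS lies in the promoter-state fragment,
and drops genes not expressed in any of the configured cell types. The
surviving genes are the high-confidence candidate causal genes for the
locus, each carried with its full evidence chain.

Enhancer/promoter state sets default to the Roadmap 15-state ChromHMM
mnemonics for enhancers ({6_EnhG, 7_Enh, 12_EnhBiv}) and active/bivalent
TSS states ({1_TssA, 2_TssAFlnk, 10_TssBiv}); both are configurable.
"""
from __future__ import annotations

import logging
from collections import defaultdict

from intervaltree import IntervalTree

from .model import (
    CandidateGene,
    ChromatinSegment,
    ExpressionRecord,
    FragmentMap,
    FragmentStateCall,
    GeneRecord,
    GenomicInterval,
    Interaction,
    LdBlock,
    PipelineError,
    RestrictionFragment,
    SnpRecord,
)

logger = logging.getLogger(__name__)

ENHANCER_STATES = frozenset({"6_EnhG", "7_Enh", "12_EnhBiv"})
PROMOTER_STATES = frozenset({"1_TssA", "2_TssAFlnk", "10_TssBiv"})

#: Roadmap 15-state mnemonics; unknown labels are warned about and ignored.
STATE_VOCABULARY = frozenset(
    {
        "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG",
        "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk",
        "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
    }
)


def build_ld_blocks(
    snps: list[SnpRecord],
    r2_threshold: float,
    fragment_map: FragmentMap | None = None,
) -> list[LdBlock]:
    """Group SNPs into one LD block per (index SNP, disease), keeping members
    with r2 >= threshold, and attach the fragments any member overlaps."""
    index_keys = {(s.snp_id, s.disease) for s in snps if s.snp_id == s.index_snp_id}
    for snp in snps:
        if (snp.index_snp_id, snp.disease) not in index_keys:
            raise PipelineError(
                f"proxy {snp.snp_id} references unknown index SNP "
                f"{snp.index_snp_id} for disease {snp.disease}"
            )
    grouped: dict[tuple[str, str], list[SnpRecord]] = defaultdict(list)
    for snp in snps:
        if snp.r2 >= r2_threshold:
            grouped[(snp.index_snp_id, snp.disease)].append(snp)
    blocks = []
    for (index_id, disease) in sorted(index_keys):
        members = sorted(grouped.get((index_id, disease), []), key=lambda s: (s.pos, s.snp_id))
        if not members:  # index itself always passes (r2 = 1)
            continue
        span = GenomicInterval(
            members[0].chrom, min(s.pos0 for s in members), max(s.pos0 for s in members) + 1
        )
        block = LdBlock(index_id, disease, members, span)
        if fragment_map is not None:
            block.fragments = assign_fragments(
                [(s.chrom, s.pos0) for s in members], fragment_map
            )
        blocks.append(block)
    return blocks


def assign_fragments(query, fragment_map: FragmentMap) -> list[RestrictionFragment]:
    """Fragments overlapping the query: either a GenomicInterval or a list of
    (chrom, 0-based position) points. Uncovered positions yield nothing."""
    if isinstance(query, GenomicInterval):
        return fragment_map.overlapping(query)
    found: dict[str, RestrictionFragment] = {}
    for chrom, pos0 in query:
        frag = fragment_map.at(chrom, pos0)
        if frag is None:
            logger.debug("position %s:%d not covered by fragment map", chrom, pos0)
            continue
        found[frag.fragment_id] = frag
    return sorted(found.values(), key=lambda f: f.interval)


class StateIndex:
    """Per-cell-type interval index over chromatin-state segments, for
    overlap-based enhancer/promoter calls on fragments."""

    def __init__(
        self,
        segments: list[ChromatinSegment],
        enhancer_states: frozenset[str] = ENHANCER_STATES,
        promoter_states: frozenset[str] = PROMOTER_STATES,
        min_overlap: int = 1,
    ):
        self.enhancer_states = frozenset(enhancer_states)
        self.promoter_states = frozenset(promoter_states)
        self.min_overlap = min_overlap
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.cell_types: set[str] = set()
        for seg in segments:
            if seg.state not in STATE_VOCABULARY:
                logger.warning(
                    "unknown chromatin state %r (%s); treated as neither "
                    "enhancer nor promoter", seg.state, seg.cell_type,
                )
            self.cell_types.add(seg.cell_type)
            self._trees[(seg.cell_type, seg.interval.chrom)].addi(
                seg.interval.start, seg.interval.end, seg.state
            )

    def call(self, fragment: RestrictionFragment, cell_type: str) -> FragmentStateCall:
        iv = fragment.interval
        tree = self._trees.get((cell_type, iv.chrom))
        enh_bp = prom_bp = 0
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                bp = min(hit.end, iv.end) - max(hit.begin, iv.start)
                if hit.data in self.enhancer_states:
                    enh_bp = max(enh_bp, bp)
                if hit.data in self.promoter_states:
                    prom_bp = max(prom_bp, bp)
        return FragmentStateCall(
            fragment.fragment_id, cell_type,
            has_enhancer=enh_bp >= self.min_overlap,
            has_promoter=prom_bp >= self.min_overlap,
        )


def call_fragment_states(
    fragment: RestrictionFragment,
    segments: list[ChromatinSegment],
    enhancer_states: frozenset[str],
    promoter_states: frozenset[str],
    cell_type: str,
    min_overlap: int = 1,
) -> FragmentStateCall:
    """Single-fragment enhancer/promoter call (convenience over StateIndex)."""
    index = StateIndex(
        [s for s in segments if s.cell_type == cell_type],
        enhancer_states, promoter_states, min_overlap,
    )
    return index.call(fragment, cell_type)


def _tss_index(genes: list[GeneRecord], fragment_map: FragmentMap) -> dict[str, list[GeneRecord]]:
    by_fragment: dict[str, list[GeneRecord]] = defaultdict(list)
    for gene in genes:
        frag = fragment_map.at(gene.tss.chrom, gene.tss.start)
        if frag is not None:
            by_fragment[frag.fragment_id].append(gene)
    return by_fragment


def _body_index(genes: list[GeneRecord], fragment_map: FragmentMap) -> dict[str, list[GeneRecord]]:
    by_fragment: dict[str, list[GeneRecord]] = defaultdict(list)
    for gene in genes:
        for frag in fragment_map.overlapping(gene.body):
            by_fragment[frag.fragment_id].append(gene)
    return by_fragment


def expressed_cell_types(
    expression: list[ExpressionRecord], cell_types: set[str] | None = None
) -> dict[str, set[str]]:
    """gene -> cell types (restricted to ``cell_types`` if given) in which the
    gene passes the expression threshold."""
    out: dict[str, set[str]] = defaultdict(set)
    for rec in expression:
        if rec.expressed and (cell_types is None or rec.cell_type in cell_types):
            out[rec.gene_id].add(rec.cell_type)
    return out


def filter_candidates(
    ld_blocks: list[LdBlock],
    interactions: list[Interaction],
    state_index: StateIndex,
    genes: list[GeneRecord],
    expression: list[ExpressionRecord],
    fragment_map: FragmentMap,
    score_threshold: float = 5.0,
    cell_types: set[str] | None = None,
    gene_mode: str = "tss",
) -> list[CandidateGene]:
    """Apply the enhancer-promoter interaction filter and return candidate
    genes with evidence.

    The filter is orientation-free: the LD-block fragment may be either the
    bait or the other end of an interaction. ``gene_mode`` selects TSS-in-
    fragment gene extraction (default) or gene-body overlap.
    """
    if gene_mode not in ("tss", "body"):
        raise ValueError(f"gene_mode must be 'tss' or 'body', got {gene_mode!r}")
    gene_index = (
        _tss_index(genes, fragment_map) if gene_mode == "tss"
        else _body_index(genes, fragment_map)
    )
    if cell_types is None:
        cell_types = set(state_index.cell_types) | {i.cell_type for i in interactions}
    expr = expressed_cell_types(expression, cell_types)

    by_fragment: dict[str, list[Interaction]] = defaultdict(list)
    for inter in interactions:
        if inter.cell_type not in cell_types or inter.score < score_threshold:
            continue
        by_fragment[inter.bait.fragment_id].append(inter)
        by_fragment[inter.other_end.fragment_id].append(inter)

    state_cache: dict[tuple[str, str], FragmentStateCall] = {}

    def state_of(frag: RestrictionFragment, cell_type: str) -> FragmentStateCall:
        key = (frag.fragment_id, cell_type)
        if key not in state_cache:
            state_cache[key] = state_index.call(frag, cell_type)
        return state_cache[key]

    found: dict[tuple[str, str, str], CandidateGene] = {}
    for block in ld_blocks:
        seen_pairs: set[tuple[str, str, str]] = set()
        for block_frag in block.fragments:
            for inter in by_fragment.get(block_frag.fragment_id, []):
                partner = inter.partner_of(block_frag.fragment_id)
                if partner is None:
                    continue
                pair_key = (block_frag.fragment_id, partner.fragment_id, inter.cell_type)
                if pair_key in seen_pairs:
                    continue
                seen_pairs.add(pair_key)
                if not state_of(block_frag, inter.cell_type).has_enhancer:
                    continue
                if not state_of(partner, inter.cell_type).has_promoter:
                    continue
                for gene in gene_index.get(partner.fragment_id, []):
                    expressed_in = expr.get(gene.gene_id, set())
                    if not expressed_in:
                        continue
                    key = (gene.gene_id, block.index_snp_id, block.disease)
                    cand = found.get(key)
                    if cand is None:
                        cand = CandidateGene(
                            gene.gene_id, block.disease, block.index_snp_id,
                            set(), [], set(expressed_in),
                        )
                        found[key] = cand
                    cand.cell_types.add(inter.cell_type)
                    cand.interactions.append(
                        (inter, block_frag.fragment_id, partner.fragment_id)
                    )
    return sorted(found.values(), key=lambda c: (c.disease, c.index_snp_id, c.gene_id))


def candidate_gene_sets(candidates: list[CandidateGene]) -> dict[str, set[str]]:
    """Candidate genes pooled per disease."""
    out: dict[str, set[str]] = defaultdict(set)
    for cand in candidates:
        out[cand.disease].add(cand.gene_id)
    return dict(out)


def candidates_by_locus(candidates: list[CandidateGene]) -> dict[tuple[str, str], set[str]]:
    """Candidate genes per (index SNP, disease) locus."""
    out: dict[tuple[str, str], set[str]] = defaultdict(set)
    for cand in candidates:
        out[(cand.index_snp_id, cand.disease)].add(cand.gene_id)
    return dict(out)
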
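"""Synthetic dataset generator with planted ground truth.

Emulates the study design end to end on a toy genome: a restriction-digest
fragment map (~4 kb fragments), GWAS index SNPs with LD proxies (r2 drawn
on [0.5, 1.0] so the r2 >= 0.8 cut is exercised on both sides), ChromHMM
state tracks and expression for two cell types, CHICAGO-style interaction
calls, a DrugBank-like drug-target table and a GMT pathway collection with
one planted enriched pathway per disease.

Every locus is built as one of six archetypes:

- POSITIVE      — LD SNP in an enhancer-state fragment interacting (score
                  above threshold) with promoter-state fragments holding
                  expressed gene TSSs; sub-kinds vary the candidate count
                  and whether the reported GWAS gene is recovered, so every
                  comparison category is populated;
- REPORTED_ONLY — positive locus whose single candidate is the reported gene;
- NO_ENHANCER   — the SNP fragment carries no enhancer state;
- NO_PROMOTER   — the other end carries no promoter state (enhancer instead);
- NOT_EXPRESSED — the target gene is below the expression threshold in both
                  cell types;
- NO_INTERACTION— the interaction score falls below the score threshold.

Locus windows are separated by >=60 kb, beyond the +/-50 kb proxy reach, so
no locus can borrow evidence from a neighbour: the planted expectations are
exact by construction, and an independent brute-force replay of the filter
confirms them in the test suite.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .model import (
    ChromatinSegment,
    DiseaseTermSet,
    DrugTargetRecord,
    ExpressionRecord,
    FragmentMap,
    GeneRecord,
    GenomicInterval,
    Interaction,
    PathwaySet,
    PipelineError,
    RestrictionFragment,
    SnpRecord,
)

POSITIVE = "POSITIVE"
REPORTED_ONLY = "REPORTED_ONLY"
NO_ENHANCER = "NO_ENHANCER"
NO_PROMOTER = "NO_PROMOTER"
NOT_EXPRESSED = "NOT_EXPRESSED"
NO_INTERACTION = "NO_INTERACTION"
ARCHETYPES = (
    POSITIVE, REPORTED_ONLY, NO_ENHANCER, NO_PROMOTER, NOT_EXPRESSED, NO_INTERACTION,
)

_ENH_CYCLE = ("7_Enh", "6_EnhG", "12_EnhBiv")
_PROM_CYCLE = ("1_TssA", "2_TssAFlnk", "10_TssBiv")

_WINDOW_FRAGS = 16
_GAP_BP = 60_000  # > proxy reach of 50 kb, so loci cannot interfere
_PROXY_REACH = 50_000


class GenerationError(PipelineError):
    """The requested fixture does not fit the configured genome."""


@dataclass
class FixtureConfig:
    """Parameters of the synthetic study; defaults are the study conditions
    every test and the acceptance run use."""

    n_loci: int = 22  # per disease; 3 diseases -> 66 loci
    n_proxies: int = 5
    fragment_mean_bp: int = 4000
    chrom_sizes: dict = field(
        default_factory=lambda: {
            "chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000,
        }
    )
    diseases: tuple = ("RA", "PsA", "JIA")
    cell_types: tuple = ("GM12878", "Tcell")
    r2_threshold: float = 0.8
    score_threshold: float = 5.0
    expression_threshold: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    locus_archetype_mix: dict = field(
        default_factory=lambda: {
            POSITIVE: 0.35, REPORTED_ONLY: 0.15, NO_ENHANCER: 0.125,
            NO_PROMOTER: 0.125, NOT_EXPRESSED: 0.125, NO_INTERACTION: 0.125,
        }
    )
    multi_gene_promoter: bool = True

    def __post_init__(self):
        total = sum(self.locus_archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"archetype proportions sum to {total}, not 1")
        if self.n_loci < 0 or self.n_proxies < 0:
            raise GenerationError("counts must be >= 0")
        unknown = set(self.locus_archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise GenerationError(f"unknown archetypes {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted expectations, consistent with the generated files by
    construction."""

    loci: list = field(default_factory=list)
    pathways: dict = field(default_factory=dict)
    drugs: dict = field(default_factory=dict)
    expected_refined: dict = field(default_factory=dict)
    expected_expanded: dict = field(default_factory=dict)

    def candidates_by_locus(self) -> dict:
        return {
            (l["index_snp_id"], l["disease"]): set(l["expected_candidates"])
            for l in self.loci
        }

    def candidates_by_disease(self) -> dict:
        out: dict[str, set] = {}
        for locus in self.loci:
            out.setdefault(locus["disease"], set()).update(locus["expected_candidates"])
        return out

    def category_counts(self) -> dict:
        out: dict[str, dict[str, int]] = {}
        for locus in self.loci:
            by_disease = out.setdefault(locus["disease"], {})
            cat = locus["expected_category"]
            by_disease[cat] = by_disease.get(cat, 0) + 1
        return out

    def to_json(self, path) -> None:
        data = {
            "loci": self.loci,
            "pathways": self.pathways,
            "drugs": self.drugs,
            "expected_refined": self.expected_refined,
            "expected_expanded": self.expected_expanded,
        }
        with open(path, "w") as out:
            json.dump(data, out, indent=1, sort_keys=True)
            out.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


def _apportion(n: int, mix: dict) -> dict:
    """Largest-remainder apportionment of n loci over archetypes."""
    shares = {a: n * mix.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(share) for a, share in shares.items()}
    remainder = n - sum(counts.values())
    order = sorted(ARCHETYPES, key=lambda a: shares[a] - counts[a], reverse=True)
    for a in order[:remainder]:
        counts[a] += 1
    return counts


def _tile_fragments(cfg: FixtureConfig, rng) -> list[RestrictionFragment]:
    frags = []
    counter = 1
    low, high = cfg.fragment_mean_bp // 2, cfg.fragment_mean_bp * 3 // 2
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        pos = 0
        while pos < size:
            length = int(rng.integers(low, high + 1))
            end = min(pos + length, size)
            if size - end < low:  # absorb the stub into the last fragment
                end = size
            frags.append(
                RestrictionFragment(GenomicInterval(chrom, pos, end), f"F{counter:06d}")
            )
            counter += 1
            pos = end
    return frags


def _carve_windows(fragments: list[RestrictionFragment], n_windows: int):
    """Disjoint runs of _WINDOW_FRAGS fragments separated by >=_GAP_BP, and
    never closer than the proxy reach to a chromosome edge."""
    windows = []
    by_chrom: dict[str, list[RestrictionFragment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.interval.chrom, []).append(frag)
    for chrom in sorted(by_chrom):
        frags = by_chrom[chrom]
        i = 0
        # keep clear of the chromosome start so proxies stay on-chromosome
        while i < len(frags) and frags[i].interval.end < _PROXY_REACH:
            i += 1
        while i + _WINDOW_FRAGS <= len(frags):
            window = frags[i : i + _WINDOW_FRAGS]
            i += _WINDOW_FRAGS
            gap_start = frags[i - 1].interval.end
            while i < len(frags) and frags[i].interval.start < gap_start + _GAP_BP:
                i += 1
            if window[-1].interval.end + _PROXY_REACH <= frags[-1].interval.end:
                windows.append(window)
            if len(windows) == n_windows:
                return windows
    raise GenerationError(
        f"genome holds only {len(windows)} locus windows, need {n_windows}"
    )


def _mid(frag: RestrictionFragment) -> int:
    return (frag.interval.start + frag.interval.end) // 2


class _Builder:
    def __init__(self, cfg: FixtureConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.snps: list[SnpRecord] = []
        self.segments: dict[str, list[ChromatinSegment]] = {c: [] for c in cfg.cell_types}
        self.genes: list[GeneRecord] = []
        self.expression: list[ExpressionRecord] = []
        self.interactions: list[Interaction] = []
        self.reported: dict[tuple[str, str], tuple[str, ...]] = {}
        self.truth = GroundTruth()
        self._gene_counter = 0
        self._inert_counter = 0
        self._snp_counter = 0

    # -- naming ---------------------------------------------------------
    def new_gene(self) -> str:
        self._gene_counter += 1
        return f"G{self._gene_counter:04d}"

    def new_inert_gene(self) -> str:
        self._inert_counter += 1
        return f"R{self._inert_counter:04d}"

    def new_rsid(self) -> str:
        self._snp_counter += 1
        return f"rs{100000 + self._snp_counter}"

    # -- placement ------------------------------------------------------
    def add_state(self, frag: RestrictionFragment, state: str) -> None:
        iv = frag.interval
        pad = min(100, (len(iv) - 2) // 2)
        seg_iv = GenomicInterval(iv.chrom, iv.start + pad, iv.end - pad)
        for cell in self.cfg.cell_types:
            self.segments[cell].append(ChromatinSegment(seg_iv, state, cell))

    def add_gene(self, symbol: str, frag: RestrictionFragment, slot: int, n_slots: int) -> None:
        iv = frag.interval
        usable = len(iv) - 200
        offset = 100 + (usable * (2 * slot + 1)) // (2 * n_slots)
        tss = iv.start + offset
        strand = "+" if self.rng.integers(2) == 0 else "-"
        if strand == "+":
            body = GenomicInterval(iv.chrom, tss, tss + 1500)
        else:
            body = GenomicInterval(iv.chrom, max(tss + 1 - 1500, 0), tss + 1)
        self.genes.append(
            GeneRecord(symbol, GenomicInterval(iv.chrom, tss, tss + 1), body, strand)
        )

    def add_expression(self, symbol: str, expressed: bool) -> None:
        thr = self.cfg.expression_threshold
        for cell in self.cfg.cell_types:
            if expressed:
                value = round(float(self.rng.uniform(thr + 4, thr + 99)), 2)
            else:
                value = round(float(self.rng.uniform(0, thr * 0.5)), 2)
            self.expression.append(ExpressionRecord(symbol, cell, value, value >= thr))

    def add_interaction(self, bait, oe, high: bool) -> None:
        st = self.cfg.score_threshold
        for cell in self.cfg.cell_types:
            if high:
                score = round(float(self.rng.uniform(st + 1, st + 10)), 2)
            else:
                score = round(float(self.rng.uniform(0.5, st * 0.7)), 2)
            self.interactions.append(Interaction(bait, oe, score, cell))

    def add_snps(self, index_id: str, disease: str, enh_frag: RestrictionFragment) -> None:
        chrom = enh_frag.interval.chrom
        chrom_size = self.cfg.chrom_sizes[chrom]
        index_pos = _mid(enh_frag) + 1  # 1-based
        self.snps.append(SnpRecord(index_id, chrom, index_pos, 1.0, index_id, disease))
        for _ in range(self.cfg.n_proxies):
            offset = int(self.rng.integers(-_PROXY_REACH, _PROXY_REACH + 1))
            pos = int(np.clip(index_pos + offset, 1, chrom_size))
            r2 = round(float(self.rng.uniform(0.5, 1.0)), 3)
            self.snps.append(SnpRecord(self.new_rsid(), chrom, pos, r2, index_id, disease))


def _plant_locus(b: _Builder, disease: str, archetype: str, subkind: str | None,
                 i: int, window: list[RestrictionFragment]) -> dict:
    cfg = b.cfg
    enh_frag = window[0]
    promoter_slots = window[2:15:2]  # up to 7 fragments
    inert_frag, decoy_frag = window[15], window[13]
    index_id = b.new_rsid()
    b.add_snps(index_id, disease, enh_frag)

    # enhancer side chromatin state
    if archetype == NO_ENHANCER:
        b.add_state(enh_frag, "15_Quies")
    else:
        b.add_state(enh_frag, _ENH_CYCLE[i % len(_ENH_CYCLE)])

    # how many genes, and which states/wiring survive
    if archetype in (POSITIVE,):
        if subkind == "cat0":
            n_genes = 1 + i % 3
        elif subkind == "cat25":
            n_genes = 2 + i % 4
        else:  # cat6plus
            n_genes = 6 + i % 2
    else:
        n_genes = 1
    max_per_frag = 2 if cfg.multi_gene_promoter else 1
    n_slots = min(len(promoter_slots), max(1, -(-n_genes // max_per_frag)))
    used_slots = promoter_slots[:n_slots]

    genes = [b.new_gene() for _ in range(n_genes)]
    per_slot: dict[str, list[str]] = {f.fragment_id: [] for f in used_slots}
    for j, symbol in enumerate(genes):
        per_slot[used_slots[j % n_slots].fragment_id].append(symbol)
    for slot in used_slots:
        members = per_slot[slot.fragment_id]
        state = "7_Enh" if archetype == NO_PROMOTER else _PROM_CYCLE[i % len(_PROM_CYCLE)]
        b.add_state(slot, state)
        for s_idx, symbol in enumerate(members):
            b.add_gene(symbol, slot, s_idx, len(members))
            b.add_expression(symbol, expressed=archetype != NOT_EXPRESSED)
        b.add_interaction(enh_frag, slot, high=archetype != NO_INTERACTION)

    # a stateless decoy interaction exercising the removal classes
    b.add_interaction(enh_frag, decoy_frag, high=True)

    # reported GWAS gene
    if archetype == POSITIVE and subkind == "cat0":
        reported = b.new_inert_gene()
        b.add_gene(reported, inert_frag, 0, 1)
        b.add_expression(reported, expressed=True)
    elif archetype in (REPORTED_ONLY,) or (archetype == POSITIVE):
        reported = genes[i % n_genes]
    else:
        # failing archetypes still carry a reported label (the planted gene)
        reported = genes[0]
    b.reported[(index_id, disease)] = (reported,)

    if archetype in (POSITIVE, REPORTED_ONLY):
        expected = sorted(genes)
        if archetype == REPORTED_ONLY:
            category = "1"
        elif subkind == "cat0":
            category = "0"
        else:
            category = "2-5" if n_genes <= 5 else "6+"
    else:
        expected = []
        category = "no_chic_genes"
    return {
        "index_snp_id": index_id,
        "disease": disease,
        "archetype": archetype if subkind is None else f"{archetype}:{subkind}",
        "expected_candidates": expected,
        "reported_genes": [reported],
        "expected_category": category,
    }


def _plant_drugs(b: _Builder) -> list[DrugTargetRecord]:
    cfg = b.cfg
    terms = default_disease_terms()
    term_by_disease = {t.disease: t.terms[0] for t in terms}
    records: list[DrugTargetRecord] = []
    counter = 0
    repo_texts = (
        "Used in the treatment of multiple sclerosis.",
        "Treatment of chronic lymphocytic leukaemia and lymphoma.",
        "",
        "Management of hypertension in adults.",
    )
    for disease in cfg.diseases:
        genes = sorted(b.truth.candidates_by_disease().get(disease, set()))
        targets = genes[::2]  # every other candidate gene is a drug target
        j = 0
        while j < len(targets):
            counter += 1
            drug_id, name = f"DB{10000 + counter}", f"drug{counter:03d}"
            hit = [targets[j]]
            # occasionally one drug hits two candidate genes
            if j + 1 < len(targets) and counter % 4 == 1:
                hit.append(targets[j + 1])
                j += 1
            j += 1
            if counter % 3 == 0:
                indication = (
                    f"Indicated for the treatment of {term_by_disease[disease]} "
                    "and related inflammatory conditions."
                )
                classification = "current"
            else:
                indication = repo_texts[counter % len(repo_texts)]
                classification = "repositionable"
            groups = frozenset(
                {"approved"} if counter % 5 else {"approved", "investigational"}
            )
            for gene in hit:
                records.append(DrugTargetRecord(drug_id, name, gene, groups, indication))
            b.truth.drugs[drug_id] = {
                "disease": disease,
                "classification": classification,
                "target_genes": sorted(hit),
            }
    # drugs whose targets are not candidates anywhere
    inert = [g.gene_id for g in b.genes if g.gene_id.startswith("R")][:4]
    for gene in inert:
        counter += 1
        drug_id = f"DB{10000 + counter}"
        records.append(
            DrugTargetRecord(
                drug_id, f"drug{counter:03d}", gene, frozenset({"approved"}),
                "Used in the treatment of melanoma.",
            )
        )
        b.truth.drugs[drug_id] = {
            "disease": None, "classification": "absent", "target_genes": [gene],
        }
    return records


def _plant_pathways(b: _Builder) -> list[PathwaySet]:
    rng = b.rng
    pool = [f"BG{i:04d}" for i in range(1, 151)]
    pathways = []
    by_disease = b.truth.candidates_by_disease()
    for disease in b.cfg.diseases:
        genes = sorted(by_disease.get(disease, set()))
        n_members = max(2, int(round(0.6 * len(genes))))
        members = sorted(
            rng.choice(genes, size=min(n_members, len(genes)), replace=False).tolist()
        )
        filler = sorted(rng.choice(pool, size=8, replace=False).tolist())
        pw_id = f"PW_{disease}"
        pathways.append(
            PathwaySet(pw_id, f"{disease} planted signalling", frozenset(members + filler))
        )
        b.truth.pathways[pw_id] = {
            "disease": disease, "enriched": True, "genes": sorted(members + filler),
        }
        b.truth.expected_refined[disease] = members
        b.truth.expected_expanded[disease] = sorted(members + filler)
    for i in range(1, 11):
        size = int(rng.integers(15, 36))
        genes = sorted(rng.choice(pool, size=size, replace=False).tolist())
        pw_id = f"PW_BG{i:02d}"
        pathways.append(PathwaySet(pw_id, f"background pathway {i}", frozenset(genes)))
        b.truth.pathways[pw_id] = {"disease": None, "enriched": False, "genes": genes}
    return pathways


def default_disease_terms() -> list[DiseaseTermSet]:
    return [
        DiseaseTermSet("JIA", ("juvenile idiopathic arthritis", "juvenile arthritis")),
        DiseaseTermSet("PsA", ("psoriatic arthritis",)),
        DiseaseTermSet("RA", ("rheumatoid arthritis",)),
    ]


def generate_fixture(config: FixtureConfig, outdir) -> GroundTruth:
    """Generate the complete dataset under ``outdir`` and return (and write)
    the planted ground truth. Identical config and seed give byte-identical
    files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    b = _Builder(config, rng)

    fragments = _tile_fragments(config, rng)
    fragment_map = FragmentMap(fragments)
    windows = _carve_windows(fragments, config.n_loci * len(config.diseases))

    positive_cycle = ("cat0", "cat25", "cat6plus")
    w = 0
    for disease in config.diseases:
        counts = _apportion(config.n_loci, config.locus_archetype_mix)
        pos_i = 0
        for archetype in ARCHETYPES:
            for i in range(counts[archetype]):
                subkind = None
                if archetype == POSITIVE:
                    subkind = positive_cycle[pos_i % len(positive_cycle)]
                    pos_i += 1
                locus = _plant_locus(b, disease, archetype, subkind, w, windows[w])
                b.truth.loci.append(locus)
                w += 1

    drug_records = _plant_drugs(b)
    pathways = _plant_pathways(b)
    terms = default_disease_terms()

    cio.write_fragments(fragment_map, outdir / "fragments.bed")
    for cell in config.cell_types:
        cio.write_segments(b.segments[cell], outdir / f"states_{cell}.bed")
    cio.write_genes(b.genes, outdir / "genes.bed")
    cio.write_snps(b.snps, outdir / "snps.tsv")
    cio.write_expression(b.expression, outdir / "expression.tsv")
    cio.write_interactions(b.interactions, outdir / "interactions.tsv")
    cio.write_drug_targets(drug_records, outdir / "drug_targets.tsv")
    cio.write_reported_genes(b.reported, outdir / "reported_genes.tsv")
    cio.write_gmt(pathways, outdir / "pathways.gmt")
    cio.write_disease_terms(terms, outdir / "disease_terms.yaml")
    b.truth.to_json(outdir / "ground_truth.json")

    run_config = {
        "fragments": "fragments.bed",
        "states": {cell: f"states_{cell}.bed" for cell in config.cell_types},
        "genes": "genes.bed",
        "snps": "snps.tsv",
        "expression": "expression.tsv",
        "interactions": "interactions.tsv",
        "drug_table": "drug_targets.tsv",
        "reported_genes": "reported_genes.tsv",
        "pathways": "pathways.gmt",
        "disease_terms": "disease_terms.yaml",
        "r2_threshold": config.r2_threshold,
        "score_threshold": config.score_threshold,
        "expression_threshold": config.expression_threshold,
        "alpha": config.alpha,
        "min_overlap": 1,
        "match_mode": "substring",
        "gene_mode": "tss",
        "cell_types": list(config.cell_types),
        "seed": config.seed,
    }
    with open(outdir / "config.yaml", "w") as out:
        yaml.safe_dump(run_config, out, sort_keys=True)
    return b.truth


def load_fixture_config(path) -> FixtureConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    known = {f.name for f in dataclasses.fields(FixtureConfig)}
    unknown = set(data) - known
    if unknown:
        raise GenerationError(f"unknown fixture-config keys {sorted(unknown)}")
    if "diseases" in data:
        data["diseases"] = tuple(data["diseases"])
    if "cell_types" in data:
        data["cell_types"] = tuple(data["cell_types"])
    return FixtureConfig(**data)
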
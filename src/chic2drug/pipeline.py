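"""End-to-end pipeline: candidates -> GWAS comparison -> drugs ->
enrichment -> refinement, with a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .candidates import (
    ENHANCER_STATES,
    PROMOTER_STATES,
    StateIndex,
    build_ld_blocks,
    candidate_gene_sets,
    candidates_by_locus,
    filter_candidates,
)
from .drugs import classify_current_use, drug_calls_table, map_drug_targets, summarize_targets
from .enrichment import (
    cell_type_label,
    enrich,
    enrichment_table,
    refine_and_expand,
    refinement_summary,
)
from .gwas import categorize_loci, summarize_categories
from .model import PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run. Paths are resolved
    relative to the config file's directory."""

    fragments: str
    states: dict  # cell type -> BED path
    genes: str
    snps: str
    expression: str
    interactions: str
    drug_table: str
    reported_genes: str
    pathways: str
    disease_terms: str
    r2_threshold: float = 0.8
    score_threshold: float = 5.0
    expression_threshold: float = 1.0
    alpha: float = 0.05
    min_overlap: int = 1
    match_mode: str = "substring"
    gene_mode: str = "tss"
    groups: list | None = None  # e.g. ["approved"]; None = no filter
    enhancer_states: list = field(default_factory=lambda: sorted(ENHANCER_STATES))
    promoter_states: list = field(default_factory=lambda: sorted(PROMOTER_STATES))
    cell_types: list = field(default_factory=lambda: ["GM12878", "Tcell"])
    universe: str = "gmt"  # or "annotated" / "expressed"
    seed: int = 0
    base_dir: Path = field(default_factory=Path, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValidationError("r2_threshold must lie in [0, 1]")
        if self.score_threshold < 0 or self.expression_threshold < 0:
            raise ValidationError("score and expression thresholds must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        if self.match_mode not in ("substring", "token_subset"):
            raise ValidationError(f"unknown match_mode {self.match_mode!r}")
        if self.gene_mode not in ("tss", "body"):
            raise ValidationError(f"unknown gene_mode {self.gene_mode!r}")
        if self.universe not in ("gmt", "annotated", "expressed"):
            raise ValidationError(f"unknown universe {self.universe!r}")
        if not self.cell_types:
            raise ValidationError("at least one cell type is required")

    def path(self, name: str) -> Path:
        return self.base_dir / getattr(self, name)

    def state_paths(self) -> dict[str, Path]:
        return {cell: self.base_dir / p for cell, p in self.states.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(base_dir=path.parent, **data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write all result tables plus a manifest.

    Returns a dict with the in-memory results keyed by stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        fragment_map = cio.read_fragments(config.path("fragments"))
        segments = []
        for cell, path in sorted(config.state_paths().items()):
            segments.extend(cio.read_segments(path, cell))
        genes = cio.read_genes(config.path("genes"))
        snps = cio.read_snps(config.path("snps"))
        expression = cio.read_expression(
            config.path("expression"), config.expression_threshold
        )
        interactions = cio.read_interactions(config.path("interactions"), fragment_map)
        drug_table = cio.read_drug_targets(config.path("drug_table"))
        reported = cio.read_reported_genes(config.path("reported_genes"))
        pathways = cio.read_gmt(config.path("pathways"))
        disease_terms = cio.read_disease_terms(config.path("disease_terms"))

        stage = "candidates"
        state_index = StateIndex(
            segments,
            frozenset(config.enhancer_states),
            frozenset(config.promoter_states),
            config.min_overlap,
        )
        blocks = build_ld_blocks(snps, config.r2_threshold, fragment_map)
        cell_types = set(config.cell_types)
        candidates = filter_candidates(
            blocks, interactions, state_index, genes, expression, fragment_map,
            config.score_threshold, cell_types, config.gene_mode,
        )
        cio.write_candidates_table(candidates, outdir / "candidates.tsv")
        by_disease = candidate_gene_sets(candidates)
        by_locus = candidates_by_locus(candidates)

        stage = "gwas_comparison"
        categories = categorize_loci(by_locus, reported)
        cat_summary = summarize_categories(categories)
        _write_tsv(cat_summary, outdir / "categories.tsv")
        cat_rows = pd.DataFrame(
            [
                {
                    "index_snp_id": c.index_snp_id,
                    "disease": c.disease,
                    "reported_genes": ",".join(c.reported_genes),
                    "n_candidates": c.n_candidates,
                    "category": c.category if c.category is not None else "NA",
                }
                for c in categories
            ]
        ).sort_values(["disease", "index_snp_id"]).reset_index(drop=True)
        _write_tsv(cat_rows, outdir / "locus_categories.tsv")
        with open(outdir / "categories.json", "w") as out:
            json.dump(
                cat_summary.set_index("disease").to_dict(orient="index"),
                out, indent=1, sort_keys=True,
            )
            out.write("\n")

        stage = "drugs"
        groups = set(config.groups) if config.groups else None
        drug_calls = map_drug_targets(by_disease, drug_table, groups)
        drug_calls = classify_current_use(
            drug_calls, disease_terms, drug_table, config.match_mode
        )
        _write_tsv(drug_calls_table(drug_calls), outdir / "drugs.tsv")
        drug_summary = summarize_targets(drug_calls, by_disease)
        _write_tsv(drug_summary, outdir / "drug_summary.tsv")

        stage = "enrichment"
        if config.universe == "annotated":
            universe = {g.gene_id for g in genes}
        elif config.universe == "expressed":
            universe = {e.gene_id for e in expression if e.expressed}
        else:
            universe = None  # union of GMT genes, per pathway collection
        enrichment: dict[str, list] = {}
        all_results = []
        for disease in sorted(by_disease):
            pooled = enrich(
                by_disease[disease], pathways, disease, universe, config.alpha
            )
            per_cell = {}
            for cell in sorted(cell_types):
                cell_genes = {
                    c.gene_id for c in candidates
                    if c.disease == disease and cell in c.cell_types
                }
                per_cell[cell] = enrich(
                    cell_genes, pathways, disease, universe, config.alpha
                )
            pooled = cell_type_label(pooled, per_cell)
            enrichment[disease] = pooled
            all_results.extend(pooled)
        _write_tsv(
            enrichment_table(all_results, candidates, drug_calls),
            outdir / "enrichment.tsv",
        )

        stage = "refinement"
        refined = refine_and_expand(
            by_disease, enrichment, pathways, drug_table, disease_terms,
            config.match_mode,
        )
        _write_tsv(refinement_summary(refined), outdir / "refined_summary.tsv")
        refined_rows = pd.DataFrame(
            [
                {
                    "disease": d,
                    "refined_genes": ",".join(sorted(r.refined_genes)),
                    "pathway_expanded_genes": ",".join(sorted(r.pathway_expanded_genes)),
                }
                for d, r in sorted(refined.items())
            ]
        )
        _write_tsv(refined_rows, outdir / "refined_genes.tsv")
    except PipelineError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "base_dir"
        },
        "inputs": {
            name: _sha256(config.path(name))
            for name in ["fragments", "genes", "snps", "expression", "interactions",
                         "drug_table", "reported_genes", "pathways", "disease_terms"]
        }
        | {f"states_{c}": _sha256(p) for c, p in sorted(config.state_paths().items())},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=1, sort_keys=True)
        out.write("\n")

    return {
        "candidates": candidates,
        "candidates_by_disease": by_disease,
        "candidates_by_locus": by_locus,
        "categories": categories,
        "category_summary": cat_summary,
        "drug_calls": drug_calls,
        "drug_summary": drug_summary,
        "enrichment": enrichment,
        "refined": refined,
        "refinement_summary": refinement_summary(refined),
    }
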
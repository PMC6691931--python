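"""Pathway enrichment of candidate genes and the pathway-based refinement
of the drug-target list.

Each pathway is tested for over-representation in a disease's candidate
gene list with a one-sided Fisher's exact test (hypergeometric upper tail)
against a gene universe, followed by Benjamini-Hochberg FDR adjustment.
Candidates lying in at least one significant pathway form the refined gene
list; the union of all significant pathways' genes forms the expanded
search space for drug repositioning.

The default universe is the union of all genes in the supplied pathway
collection (knowledge-base universe); alternatives may be passed
explicitly (e.g. all annotated or all expressed genes).
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .drugs import classify_current_use, map_drug_targets
from .model import (
    CandidateGene,
    DiseaseTermSet,
    DrugTargetRecord,
    EnrichmentResult,
    PathwaySet,
    PipelineError,
    RefinedCandidates,
    normalize_symbol,
)

LABEL_BOTH = "Both"
LABEL_POOLED_ONLY = "Pooled-only"


def fisher_enrichment(
    query_genes: set[str], pathway: PathwaySet, universe: set[str]
) -> tuple[int, int, int, int, float]:
    """One-sided over-representation p-value P(X >= k) for the overlap of a
    query gene list with a pathway, both intersected with the universe.

    Returns (k, K, n, N, p_raw) with K the pathway size, n the query size
    and N the universe size.
    """
    universe = {normalize_symbol(g) for g in universe}
    if not universe:
        raise PipelineError("empty gene universe")
    query = {normalize_symbol(g) for g in query_genes} & universe
    members = pathway.genes & universe
    k, K, n, N = len(query & members), len(members), len(query), len(universe)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p_raw = float(hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p_raw, 1.0)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags
    (significant iff adjusted p <= alpha)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise PipelineError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj, p_adj <= alpha


def enrich(
    query_genes: set[str],
    pathways: list[PathwaySet],
    disease: str,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher + BH over a pathway collection for one disease's gene list."""
    if universe is None:
        universe = set().union(*(pw.genes for pw in pathways)) if pathways else set()
    results = []
    for pw in sorted(pathways, key=lambda p: p.pathway_id):
        k, K, n, N, p_raw = fisher_enrichment(query_genes, pw, universe)
        query = {normalize_symbol(g) for g in query_genes}
        results.append(
            EnrichmentResult(
                pw.pathway_id, pw.name, disease, k, K, n, N, p_raw,
                overlap_genes=frozenset(pw.genes & query & {normalize_symbol(g) for g in universe}),
            )
        )
    if results:
        p_adj, flags = bh_adjust([r.p_raw for r in results], alpha)
        for res, adj, sig in zip(results, p_adj, flags):
            res.p_adj = float(adj)
            res.significant = bool(sig)
    return results


def cell_type_label(
    pooled: list[EnrichmentResult],
    per_cell_type: dict[str, list[EnrichmentResult]],
) -> list[EnrichmentResult]:
    """Label each pooled-significant pathway by which single-cell-type runs
    also reach significance: the cell type's own name if exactly one does,
    "Both" if both do, "Pooled-only" if neither."""
    sig_by_cell = {
        cell: {r.pathway_id for r in results if r.significant}
        for cell, results in per_cell_type.items()
    }
    for res in pooled:
        if not res.significant:
            res.cell_type_label = None
            continue
        hits = sorted(cell for cell, sig in sig_by_cell.items() if res.pathway_id in sig)
        if len(hits) >= 2:
            res.cell_type_label = LABEL_BOTH
        elif len(hits) == 1:
            res.cell_type_label = hits[0]
        else:
            res.cell_type_label = LABEL_POOLED_ONLY
    return pooled


def snp_associations_per_pathway(
    candidates: list[CandidateGene], results: list[EnrichmentResult]
) -> dict[tuple[str, str], int]:
    """Distinct index SNPs contributing at least one overlap gene, keyed by
    (disease, pathway) — the per-pathway SNP-association count."""
    loci_by_gene: dict[tuple[str, str], set[str]] = defaultdict(set)
    for cand in candidates:
        loci_by_gene[(cand.disease, cand.gene_id)].add(cand.index_snp_id)
    out = {}
    for res in results:
        snps: set[str] = set()
        for gene in res.overlap_genes:
            snps |= loci_by_gene.get((res.disease, gene), set())
        out[(res.disease, res.pathway_id)] = len(snps)
    return out


def enrichment_table(
    results: list[EnrichmentResult],
    candidates: list[CandidateGene] | None = None,
    drug_calls=None,
) -> pd.DataFrame:
    """Tabular view of enrichment results: pathway, molecules in pathway,
    adjusted p, SNP associations, interacting genes, interacting drug
    targets, cell-type label."""
    snp_counts = (
        snp_associations_per_pathway(candidates, results) if candidates else {}
    )
    target_genes: dict[str, set[str]] = defaultdict(set)
    if drug_calls:
        for disease, calls in drug_calls.items():
            for call in calls:
                target_genes[disease] |= call.target_genes
    rows = []
    for res in sorted(results, key=lambda r: (r.disease, r.p_adj, r.pathway_id)):
        rows.append(
            {
                "disease": res.disease,
                "pathway_id": res.pathway_id,
                "pathway": res.pathway_name,
                "n_molecules": res.K,
                "p_raw": res.p_raw,
                "p_adj_bh": res.p_adj,
                "significant": str(res.significant),
                "n_snp_associations": snp_counts.get((res.disease, res.pathway_id), 0),
                "n_interacting_genes": res.k,
                "n_interacting_drug_targets": len(
                    res.overlap_genes & target_genes.get(res.disease, set())
                ),
                "cell_type_label": res.cell_type_label or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["disease", "pathway_id", "pathway", "n_molecules", "p_raw",
                 "p_adj_bh", "significant", "n_snp_associations",
                 "n_interacting_genes", "n_interacting_drug_targets",
                 "cell_type_label"],
    )


def refine_and_expand(
    candidates_by_disease: dict[str, set[str]],
    enrichment: dict[str, list[EnrichmentResult]],
    pathways: list[PathwaySet],
    drug_table: list[DrugTargetRecord],
    disease_terms: list[DiseaseTermSet],
    match_mode: str = "substring",
) -> dict[str, RefinedCandidates]:
    """Per disease: restrict candidates to significant pathways, expand to
    all genes of significant pathways, and map both gene sets to drugs."""
    pw_by_id = {pw.pathway_id: pw for pw in pathways}
    out: dict[str, RefinedCandidates] = {}
    for disease in sorted(candidates_by_disease):
        genes = {normalize_symbol(g) for g in candidates_by_disease[disease]}
        sig_ids = [r.pathway_id for r in enrichment.get(disease, []) if r.significant]
        sig_union: set[str] = set()
        for pid in sig_ids:
            sig_union |= pw_by_id[pid].genes
        refined = genes & sig_union
        refined_calls = classify_current_use(
            map_drug_targets({disease: refined}, drug_table),
            disease_terms, drug_table, match_mode,
        )[disease]
        expanded_calls = classify_current_use(
            map_drug_targets({disease: sig_union}, drug_table),
            disease_terms, drug_table, match_mode,
        )[disease]
        out[disease] = RefinedCandidates(
            disease, refined, sig_union, refined_calls, expanded_calls
        )
    return out


def refinement_summary(refined: dict[str, RefinedCandidates]) -> pd.DataFrame:
    """Per-disease and overall counts for the refined candidate list and the
    pathway-expanded repositioning space."""
    rows = []
    totals = defaultdict(set)
    for disease in sorted(refined):
        r = refined[disease]
        target_genes = (
            set().union(*(c.target_genes for c in r.refined_drugs))
            if r.refined_drugs else set()
        )
        drugs = {c.drug_id for c in r.refined_drugs}
        current = {c.drug_id for c in r.refined_drugs if c.currently_used}
        expanded_targets = (
            set().union(*(c.target_genes for c in r.expanded_drugs))
            if r.expanded_drugs else set()
        )
        expanded_drugs = {c.drug_id for c in r.expanded_drugs}
        rows.append(
            {
                "disease": disease,
                "n_genes": len(r.refined_genes),
                "n_target_genes": len(target_genes),
                "n_drugs": len(drugs),
                "n_current": len(current),
                "n_repositionable": len(drugs - current),
                "n_pathway_genes": len(r.pathway_expanded_genes),
                "n_pathway_target_genes": len(expanded_targets),
                "n_pathway_drugs": len(expanded_drugs),
            }
        )
        totals["genes"] |= r.refined_genes
        totals["targets"] |= target_genes
        totals["drugs"] |= drugs
        totals["current"] |= current
        totals["pw_genes"] |= r.pathway_expanded_genes
        totals["pw_targets"] |= expanded_targets
        totals["pw_drugs"] |= expanded_drugs
    rows.append(
        {
            "disease": "all",
            "n_genes": len(totals["genes"]),
            "n_target_genes": len(totals["targets"]),
            "n_drugs": len(totals["drugs"]),
            "n_current": len(totals["current"]),
            "n_repositionable": len(totals["drugs"] - totals["current"]),
            "n_pathway_genes": len(totals["pw_genes"]),
            "n_pathway_target_genes": len(totals["pw_targets"]),
            "n_pathway_drugs": len(totals["pw_drugs"]),
        }
    )
    return pd.DataFrame(
        rows,
        columns=["disease", "n_genes", "n_target_genes", "n_drugs", "n_current",
                 "n_repositionable", "n_pathway_genes", "n_pathway_target_genes",
                 "n_pathway_drugs"],
    )
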
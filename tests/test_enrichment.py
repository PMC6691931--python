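"""Fisher enrichment, BH adjustment, cell-type labels and refinement."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from chic2drug.drugs import map_drug_targets
from chic2drug.enrichment import (
    bh_adjust,
    cell_type_label,
    enrich,
    fisher_enrichment,
    refine_and_expand,
)
from chic2drug.model import DiseaseTermSet, EnrichmentResult, PathwaySet, PipelineError


def hypergeom_tail_exact(k, N, K, n) -> Fraction:
    """P(X >= k) by exact combinatorial enumeration (independent oracle)."""
    total = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(num, total)


def bh_stepup_reference(p):
    """Independent BH step-up: running minimum of p*m/rank from the largest
    p downward, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def _pw(pathway_id, genes):
    return PathwaySet(pathway_id, pathway_id, frozenset(genes))


class TestFisher:
    def test_zero_overlap_gives_p_one(self):
        universe = {f"U{i}" for i in range(20)}
        pathway = _pw("P", {"U0", "U1", "U2"})
        k, K, n, N, p = fisher_enrichment({"U10", "U11"}, pathway, universe)
        assert (k, K, n, N) == (0, 3, 2, 20)
        assert p == 1.0

    def test_pathway_equal_to_universe_gives_p_one(self):
        universe = {f"U{i}" for i in range(10)}
        k, K, n, N, p = fisher_enrichment({"U0", "U1"}, _pw("P", universe), universe)
        assert k == n == 2 and K == N == 10
        assert p == pytest.approx(1.0)

    def test_small_table_matches_exact_enumeration(self):
        universe = {f"U{i}" for i in range(20)}
        pathway = _pw("P", {f"U{i}" for i in range(5)})
        query = {"U0", "U1", "U2", "U10"}  # k=3 of K=5, n=4, N=20
        *_, p = fisher_enrichment(query, pathway, universe)
        expected = hypergeom_tail_exact(3, 20, 5, 4)  # = 155/4845
        assert expected == Fraction(155, 4845)
        assert abs(p - float(expected)) < 1e-12

    def test_genes_outside_universe_are_dropped(self):
        universe = {"A", "B", "C", "D"}
        k, K, n, N, _ = fisher_enrichment({"A", "ZZZ"}, _pw("P", {"A", "QQQ"}), universe)
        assert (k, K, n, N) == (1, 1, 1, 4)

    def test_empty_universe_rejected(self):
        with pytest.raises(PipelineError, match="universe"):
            fisher_enrichment({"A"}, _pw("P", {"A"}), set())


class TestBH:
    def test_single_p_is_identity(self):
        adj, sig = bh_adjust([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03) and sig[0]

    def test_equal_ps_stay_equal(self):
        adj, _ = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_reference_example(self):
        adj, sig = bh_adjust([0.01, 0.02, 0.04, 0.05], alpha=0.05)
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])
        assert sig.all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(PipelineError):
            bh_adjust([0.5, 1.2])

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            size = int(rng.integers(1, 120))
            p = np.round(rng.uniform(0, 1, size=size), 6)
            adj, sig = bh_adjust(p, alpha=0.05)
            ref = bh_stepup_reference(list(p))
            assert np.allclose(adj, ref, atol=1e-12)
            assert (sig == (np.array(ref) <= 0.05)).all()


def _res(pathway_id, disease="RA", significant=True):
    return EnrichmentResult(pathway_id, pathway_id, disease, 1, 1, 1, 10, 0.01,
                            0.01, significant)


class TestCellTypeLabel:
    def test_significant_in_both_cell_types(self):
        pooled = [_res("P1")]
        labelled = cell_type_label(
            pooled, {"GM12878": [_res("P1")], "Tcell": [_res("P1")]}
        )
        assert labelled[0].cell_type_label == "Both"

    def test_significant_in_one_cell_type_names_it(self):
        pooled = [_res("P1")]
        labelled = cell_type_label(
            pooled, {"GM12878": [_res("P1")], "Tcell": [_res("P1", significant=False)]}
        )
        assert labelled[0].cell_type_label == "GM12878"

    def test_pooled_only_residual_class(self):
        pooled = [_res("P1")]
        labelled = cell_type_label(
            pooled,
            {"GM12878": [_res("P1", significant=False)],
             "Tcell": [_res("P1", significant=False)]},
        )
        assert labelled[0].cell_type_label == "Pooled-only"

    def test_non_significant_pathways_unlabelled(self):
        pooled = [_res("P1", significant=False)]
        labelled = cell_type_label(pooled, {"GM12878": [_res("P1")]})
        assert labelled[0].cell_type_label is None

    def test_fixture_planted_pathways_labelled_both(self, pipeline_results):
        for disease, results in pipeline_results["enrichment"].items():
            for res in results:
                if res.significant:
                    assert res.cell_type_label == "Both"


class TestRefinement:
    TERMS = [DiseaseTermSet("RA", ("rheumatoid arthritis",))]

    def test_no_significant_pathway_empties_everything(self):
        enrichment = {"RA": [_res("P1", significant=False)]}
        refined = refine_and_expand(
            {"RA": {"A", "B"}}, enrichment, [_pw("P1", {"A"})], [], self.TERMS
        )["RA"]
        assert refined.refined_genes == set()
        assert refined.pathway_expanded_genes == set()

    def test_all_candidates_inside_significant_pathway_is_identity(self):
        enrichment = {"RA": [_res("P1")]}
        refined = refine_and_expand(
            {"RA": {"A", "B"}}, enrichment, [_pw("P1", {"A", "B", "C"})], [], self.TERMS
        )["RA"]
        assert refined.refined_genes == {"A", "B"}
        assert refined.pathway_expanded_genes == {"A", "B", "C"}

    def test_fixture_refinement_matches_planted_pathway(self, pipeline_results, ground_truth):
        for disease, refined in pipeline_results["refined"].items():
            assert sorted(refined.refined_genes) == ground_truth.expected_refined[disease]
            assert (
                sorted(refined.pathway_expanded_genes)
                == ground_truth.expected_expanded[disease]
            )

    def test_refinement_shrinks_and_expansion_contains_refined(self, pipeline_results):
        for disease, refined in pipeline_results["refined"].items():
            candidates = pipeline_results["candidates_by_disease"][disease]
            assert refined.refined_genes <= candidates
            assert refined.refined_genes <= refined.pathway_expanded_genes


class TestEnrichOperation:
    def test_planted_pathway_is_the_only_significant_one(self, pipeline_results, ground_truth):
        for disease, results in pipeline_results["enrichment"].items():
            significant = {r.pathway_id for r in results if r.significant}
            planted = {
                pid for pid, info in ground_truth.pathways.items()
                if info["enriched"] and info["disease"] == disease
            }
            assert significant == planted

    def test_snp_association_counts_positive_for_planted(self, pipeline_results):
        from chic2drug.enrichment import snp_associations_per_pathway

        all_results = [r for rs in pipeline_results["enrichment"].values() for r in rs]
        counts = snp_associations_per_pathway(pipeline_results["candidates"], all_results)
        for res in all_results:
            # planted pathways gather SNP loci; every other count is zero
            assert (counts[(res.disease, res.pathway_id)] > 0) == res.significant

    def test_alpha_zero_yields_no_significance(self):
        universe = {f"U{i}" for i in range(10)}
        results = enrich({"U0"}, [_pw("P", {"U0"})], "RA", universe, alpha=0.0)
        assert not any(r.significant for r in results)
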
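"""The enhancer-promoter interaction filter and its building blocks."""
import numpy as np
import pytest

from chic2drug.candidates import (
    ENHANCER_STATES,
    PROMOTER_STATES,
    StateIndex,
    assign_fragments,
    build_ld_blocks,
    call_fragment_states,
    candidate_gene_sets,
    candidates_by_locus,
    filter_candidates,
)
from chic2drug.model import (
    ChromatinSegment,
    ExpressionRecord,
    FragmentMap,
    GeneRecord,
    GenomicInterval,
    Interaction,
    PipelineError,
    RestrictionFragment,
    SnpRecord,
)

from _bruteforce import fragment_at, fragments_overlapping, read_fragments_raw, replay_filter


def _frag(chrom, start, end, fid):
    return RestrictionFragment(GenomicInterval(chrom, start, end), fid)


@pytest.fixture()
def fmap():
    return FragmentMap([_frag("chr1", i * 4000, (i + 1) * 4000, f"F{i+1}") for i in range(20)])


class TestLdBlocks:
    def test_threshold_is_inclusive(self, fmap):
        snps = [
            SnpRecord("rs1", "chr1", 1000, 1.0, "rs1", "RA"),
            SnpRecord("rs2", "chr1", 2000, 0.95, "rs1", "RA"),
            SnpRecord("rs3", "chr1", 3000, 0.79, "rs1", "RA"),
        ]
        (block,) = build_ld_blocks(snps, 0.8, fmap)
        assert {s.snp_id for s in block.member_snps} == {"rs1", "rs2"}

    def test_index_without_proxies_forms_singleton_block(self, fmap):
        (block,) = build_ld_blocks([SnpRecord("rs1", "chr1", 1000, 1.0, "rs1", "RA")], 0.8, fmap)
        assert len(block.member_snps) == 1
        assert block.fragment_ids == {"F1"}

    def test_proxy_with_unknown_index_rejected(self, fmap):
        snps = [SnpRecord("rs2", "chr1", 2000, 0.9, "rsX", "RA")]
        with pytest.raises(PipelineError, match="unknown index"):
            build_ld_blocks(snps, 0.8, fmap)

    def test_membership_matches_linear_scan(self, fmap):
        rng = np.random.default_rng(3)
        snps = [SnpRecord("rs0", "chr1", 40000, 1.0, "rs0", "RA")]
        for i in range(200):
            snps.append(
                SnpRecord(
                    f"rs{i+1}", "chr1", int(rng.integers(1, 80000)),
                    round(float(rng.uniform(0, 1)), 3), "rs0", "RA",
                )
            )
        (block,) = build_ld_blocks(snps, 0.8, fmap)
        expected = {s.snp_id for s in snps if s.r2 >= 0.8}
        assert {s.snp_id for s in block.member_snps} == expected


class TestAssignFragments:
    def test_snp_position_containment(self, fmap):
        # 1-based 1500 -> 0-based 1499, inside [0, 4000)
        (frag,) = assign_fragments([("chr1", 1499)], fmap)
        assert frag.fragment_id == "F1"

    def test_half_open_boundary_interval(self, fmap):
        frags = assign_fragments(GenomicInterval("chr1", 3900, 4100), fmap)
        assert [f.fragment_id for f in frags] == ["F1", "F2"]

    def test_exact_boundary_position_belongs_to_right_fragment(self, fmap):
        (frag,) = assign_fragments([("chr1", 4000)], fmap)
        assert frag.fragment_id == "F2"

    def test_position_outside_coverage_is_empty(self, fmap):
        assert assign_fragments([("chr2", 100), ("chr1", 99999)], fmap) == []

    def test_random_queries_match_brute_force(self, fixture_dir, run_config):
        from chic2drug.io import read_fragments

        fmap = read_fragments(fixture_dir / "fragments.bed")
        raw = read_fragments_raw(fixture_dir / "fragments.bed")
        rng = np.random.default_rng(5)
        chroms = sorted({c for c, *_ in raw})
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, 3_100_000))
            got = assign_fragments([(chrom, pos)], fmap)
            expected = fragment_at(raw, chrom, pos)
            assert [(f.interval.chrom, f.interval.start, f.interval.end, f.fragment_id)
                    for f in got] == ([expected] if expected else [])


class TestStateCalls:
    def _seg(self, start, end, state, cell="Tcell"):
        return ChromatinSegment(GenomicInterval("chr1", start, end), state, cell)

    def test_enhancer_only_fragment(self):
        frag = _frag("chr1", 0, 4000, "F1")
        call = call_fragment_states(
            frag, [self._seg(1000, 2000, "7_Enh")], ENHANCER_STATES, PROMOTER_STATES, "Tcell"
        )
        assert (call.has_enhancer, call.has_promoter) == (True, False)

    def test_fragment_with_both_states(self):
        frag = _frag("chr1", 0, 4000, "F1")
        call = call_fragment_states(
            frag,
            [self._seg(0, 1000, "1_TssA"), self._seg(2000, 3000, "7_Enh")],
            ENHANCER_STATES, PROMOTER_STATES, "Tcell",
        )
        assert (call.has_enhancer, call.has_promoter) == (True, True)

    def test_quiescent_fragment_has_neither(self):
        frag = _frag("chr1", 0, 4000, "F1")
        call = call_fragment_states(
            frag, [self._seg(0, 4000, "15_Quies")], ENHANCER_STATES, PROMOTER_STATES, "Tcell"
        )
        assert (call.has_enhancer, call.has_promoter) == (False, False)

    def test_unknown_state_warned_and_ignored(self, caplog):
        frag = _frag("chr1", 0, 4000, "F1")
        with caplog.at_level("WARNING"):
            call = call_fragment_states(
                frag, [self._seg(0, 4000, "99_Bogus")], ENHANCER_STATES, PROMOTER_STATES, "Tcell"
            )
        assert (call.has_enhancer, call.has_promoter) == (False, False)
        assert "99_Bogus" in caplog.text

    def test_min_overlap_excludes_small_touches(self):
        frag = _frag("chr1", 0, 4000, "F1")
        segs = [self._seg(3990, 5000, "7_Enh")]
        index = StateIndex(segs, min_overlap=50)
        assert not index.call(frag, "Tcell").has_enhancer
        assert StateIndex(segs, min_overlap=10).call(frag, "Tcell").has_enhancer


class _Scenario:
    """Schematic region: one SNP fragment, three interactions of which only
    the enhancer-to-promoter one with an expressed gene should survive."""

    def __init__(self):
        self.fmap = FragmentMap(
            [_frag("chr1", i * 4000, (i + 1) * 4000, f"F{i+1}") for i in range(12)]
        )
        f = self.fmap.get
        self.snps = [SnpRecord("rs1", "chr1", 2000, 1.0, "rs1", "RA")]
        self.segments = [
            ChromatinSegment(GenomicInterval("chr1", 100, 3900), "7_Enh", "Tcell"),
            # F3: promoter (GENE1, not expressed); F5: quiescent (GENE2);
            # F7: promoter (GENE3, expressed)
            ChromatinSegment(GenomicInterval("chr1", 8100, 11900), "1_TssA", "Tcell"),
            ChromatinSegment(GenomicInterval("chr1", 16100, 19900), "15_Quies", "Tcell"),
            ChromatinSegment(GenomicInterval("chr1", 24100, 27900), "1_TssA", "Tcell"),
        ]
        self.genes = [
            GeneRecord("GENE1", GenomicInterval("chr1", 9000, 9001),
                       GenomicInterval("chr1", 9000, 10500), "+"),
            GeneRecord("GENE2", GenomicInterval("chr1", 17000, 17001),
                       GenomicInterval("chr1", 17000, 18500), "+"),
            GeneRecord("GENE3", GenomicInterval("chr1", 25000, 25001),
                       GenomicInterval("chr1", 25000, 26500), "+"),
        ]
        self.expression = [
            ExpressionRecord("GENE1", "Tcell", 0.0, False),
            ExpressionRecord("GENE2", "Tcell", 8.0, True),
            ExpressionRecord("GENE3", "Tcell", 9.0, True),
        ]
        self.interactions = [
            Interaction(f("F1"), f("F3"), 7.0, "Tcell"),
            Interaction(f("F1"), f("F5"), 7.0, "Tcell"),
            Interaction(f("F1"), f("F7"), 7.0, "Tcell"),
        ]

    def run(self, score_threshold=5.0, r2_threshold=0.8, expression_threshold=1.0,
            expression=None):
        blocks = build_ld_blocks(self.snps, r2_threshold, self.fmap)
        expr = expression if expression is not None else self.expression
        expr = [
            ExpressionRecord(e.gene_id, e.cell_type, e.value, e.value >= expression_threshold)
            for e in expr
        ]
        return filter_candidates(
            blocks, self.interactions, StateIndex(self.segments), self.genes,
            expr, self.fmap, score_threshold,
        )


class TestFilter:
    def test_only_expressed_enhancer_promoter_gene_retained(self):
        candidates = _Scenario().run()
        assert [c.gene_id for c in candidates] == ["GENE3"]
        (cand,) = candidates
        assert cand.interactions[0][1] == "F1" and cand.interactions[0][2] == "F7"
        assert cand.expressed_in == {"Tcell"}

    def test_enhancer_on_both_ends_yields_no_candidate(self):
        scenario = _Scenario()
        scenario.segments[3] = ChromatinSegment(
            GenomicInterval("chr1", 24100, 27900), "7_Enh", "Tcell"
        )
        assert scenario.run() == []

    def test_score_threshold_removes_weak_interactions(self):
        assert _Scenario().run(score_threshold=7.5) == []

    def test_filter_is_orientation_free(self):
        scenario = _Scenario()
        f = scenario.fmap.get
        # swap bait and other end of the informative interaction
        scenario.interactions[2] = Interaction(f("F7"), f("F1"), 7.0, "Tcell")
        assert [c.gene_id for c in scenario.run()] == ["GENE3"]

    def test_fixture_candidates_equal_ground_truth(self, pipeline_results, ground_truth):
        got = pipeline_results["candidates_by_locus"]
        expected = {k: v for k, v in ground_truth.candidates_by_locus().items() if v}
        assert got == expected

    def test_evidence_revalidates_under_brute_force(self, fixture_dir, pipeline_results):
        replayed = replay_filter(fixture_dir)
        got = pipeline_results["candidates_by_locus"]
        assert got == {k: v for k, v in replayed.items() if v}

    def test_cell_type_union(self, fixture_dir, run_config):
        """Pooled two-cell-type candidates equal the union of per-cell-type runs."""
        from chic2drug import io as cio

        fmap = cio.read_fragments(fixture_dir / "fragments.bed")
        segments = []
        for cell, path in sorted(run_config.state_paths().items()):
            segments.extend(cio.read_segments(path, cell))
        genes = cio.read_genes(fixture_dir / "genes.bed")
        expression = cio.read_expression(fixture_dir / "expression.tsv", 1.0)
        interactions = cio.read_interactions(fixture_dir / "interactions.tsv", fmap)
        blocks = build_ld_blocks(cio.read_snps(fixture_dir / "snps.tsv"), 0.8, fmap)
        index = StateIndex(segments)

        def genes_for(cells):
            cands = filter_candidates(
                blocks, interactions, index, genes, expression, fmap, 5.0, cells
            )
            return {(c.index_snp_id, c.disease, c.gene_id) for c in cands}

        pooled = genes_for({"GM12878", "Tcell"})
        assert pooled == genes_for({"GM12878"}) | genes_for({"Tcell"})

    @pytest.mark.parametrize("knob", ["score", "r2", "expression"])
    def test_raising_thresholds_never_adds_candidates(self, knob):
        scenario = _Scenario()
        scenario.snps.append(SnpRecord("rs2", "chr1", 2500, 0.85, "rs1", "RA"))
        grids = {
            "score": [0.0, 5.0, 7.5, 10.0],
            "r2": [0.5, 0.8, 0.9, 1.0],
            "expression": [0.0, 1.0, 8.5, 20.0],
        }
        previous = None
        for value in grids[knob]:
            kwargs = {f"{knob}_threshold" if knob != "r2" else "r2_threshold": value}
            current = {c.gene_id for c in scenario.run(**kwargs)}
            if previous is not None:
                assert current <= previous
            previous = current


def test_gene_body_mode_is_superset_of_tss_mode():
    scenario = _Scenario()
    blocks = build_ld_blocks(scenario.snps, 0.8, scenario.fmap)
    expr = scenario.expression
    kwargs = dict(
        interactions=scenario.interactions, state_index=StateIndex(scenario.segments),
        genes=scenario.genes, expression=expr, fragment_map=scenario.fmap,
        score_threshold=5.0,
    )
    tss = {c.gene_id for c in filter_candidates(blocks, gene_mode="tss", **kwargs)}
    body = {c.gene_id for c in filter_candidates(blocks, gene_mode="body", **kwargs)}
    assert tss <= body


def test_candidate_grouping_helpers():
    scenario = _Scenario()
    candidates = scenario.run()
    assert candidate_gene_sets(candidates) == {"RA": {"GENE3"}}
    assert candidates_by_locus(candidates) == {("rs1", "RA"): {"GENE3"}}
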
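"""Loop reproducibility pass rule, strength/length classes, differential status,
TAD context, and anchor element densities."""

from collections import Counter

import pytest

from hicrewire.domains import ConsensusDomain
from hicrewire.intervals import GenomicInterval
from hicrewire.io import CONTEXTS, ContextStats, LoopCall, RegulatoryElement
from hicrewire.loops import (
    ReproducibleLoop,
    classify_length,
    classify_strength,
    context_three_way,
    diff_loops,
    loop_tad_context,
    passes_significance,
    reproducible_loops,
)


def stats(observed=5, oe=1.2, adj_p=0.5, override=None):
    base = {c: ContextStats(observed=observed, oe=oe, adj_p=adj_p) for c in CONTEXTS}
    if override:
        base.update(override)
    return base


def loop_call(a1=2_000_000, a2=5_000_000, st=None, chrom="chr1", rep=1):
    return LoopCall(
        anchor1=GenomicInterval(chrom, a1, a1 + 10_000),
        anchor2=GenomicInterval(chrom, a2, a2 + 10_000),
        stats=st or stats(), replicate=rep,
    )


def rloop(a1, a2, condition="sham", strength="intermediate", chrom="chr1"):
    return ReproducibleLoop(
        anchor1=GenomicInterval(chrom, a1, a1 + 10_000),
        anchor2=GenomicInterval(chrom, a2, a2 + 10_000),
        stats=stats(), condition=condition, strength=strength,
        length_class=classify_length(a2 - a1),
    )


class TestPassRule:
    def test_passes_when_any_context_qualifies(self):
        s = stats(override={"Donut": ContextStats(observed=5, oe=1.0, adj_p=0.01)})
        assert passes_significance(s)

    def test_observed_two_fails(self):
        s = stats(observed=2, adj_p=0.001)
        assert not passes_significance(s)

    def test_needs_same_context_for_p_and_count(self):
        s = stats(observed=2, adj_p=0.001,
                  override={"H": ContextStats(observed=10, oe=1.0, adj_p=0.5)})
        assert not passes_significance(s)


class TestReproducibility:
    def test_present_and_passing_in_all(self):
        good = stats(override={"Donut": ContextStats(observed=5, oe=1.2, adj_p=0.01)})
        reps = [[loop_call(st=good, rep=r)] for r in (1, 2, 3)]
        assert len(reproducible_loops(reps)) == 1

    def test_missing_in_one_replicate_excluded(self):
        good = stats(override={"Donut": ContextStats(observed=5, oe=1.2, adj_p=0.01)})
        reps = [[loop_call(st=good)], [loop_call(st=good)], []]
        assert reproducible_loops(reps) == []

    def test_best_context_observed_two_excluded(self):
        good = stats(override={"Donut": ContextStats(observed=5, oe=1.2, adj_p=0.01)})
        failing = stats(observed=2, adj_p=0.01)
        reps = [[loop_call(st=good)], [loop_call(st=good)], [loop_call(st=failing)]]
        assert reproducible_loops(reps) == []

    def test_planted_decoys_excluded(self, pipeline_run):
        results, _, manifest = pipeline_run
        decoy_keys = {tuple(d["key"]) for d in manifest.data["loops"]["decoys"]}
        for cond in ("sham", "rep_6h", "rep_24h"):
            assert not decoy_keys & {l.key for l in results.reproducible_loops[cond]}


class TestStrength:
    def test_strong(self):
        s = stats(override={"Donut": ContextStats(observed=20, oe=3.0, adj_p=0.001)})
        assert classify_strength(s) == "strong"

    def test_weak(self):
        assert classify_strength(stats(observed=5, oe=1.2, adj_p=0.01)) == "weak"

    def test_intermediate(self):
        s = stats(override={"BL": ContextStats(observed=12, oe=2.0, adj_p=0.01)})
        assert classify_strength(s) == "intermediate"

    @pytest.mark.parametrize("span,expected", [(199_999, "short"), (200_000, "long"), (30_000, "short")])
    def test_length_cut(self, span, expected):
        assert classify_length(span) == expected


class TestDiffLoops:
    def _delta(self, in_sham, in_6h, in_24h):
        a1, a2 = 2_000_000, 5_000_000
        sham = [rloop(a1, a2, "sham")] if in_sham else []
        s6 = [rloop(a1, a2, "rep_6h")] if in_6h else []
        s24 = [rloop(a1, a2, "rep_24h")] if in_24h else []
        (d,) = diff_loops(sham, s6, s24)
        return d

    @pytest.mark.parametrize(
        "presence,status",
        [
            ((False, True, False), "gained_6h"),
            ((False, False, True), "gained_24h"),
            ((True, False, False), "lost"),
            ((True, True, True), "stable"),
            ((True, False, True), "stable"),
            ((True, True, False), "stable"),
        ],
    )
    def test_strict_status(self, presence, status):
        assert self._delta(*presence).status == status

    def test_per_timepoint_flags(self):
        d = self._delta(True, False, True)
        # strict mode keeps it stable; the per-timepoint reading flags it lost at 6 h
        assert d.status == "stable" and d.lost_6h and not d.lost_24h

    def test_partition_over_union(self, pipeline_run):
        results, _, _ = pipeline_run
        deltas = results.loop_deltas
        union = set()
        for cond in ("sham", "rep_6h", "rep_24h"):
            union |= {l.key for l in results.reproducible_loops[cond]}
        assert len(deltas) == len(union)
        counts = Counter(d.status for d in deltas)
        assert sum(counts.values()) == len(union)

    def test_order_invariance(self):
        loops_a = [rloop(2_000_000, 5_000_000), rloop(1_000_000, 1_200_000)]
        a = diff_loops(loops_a, [], [])
        b = diff_loops(loops_a[::-1], [], [])
        assert [d.key for d in a] == [d.key for d in b]


class TestContext:
    def _tads(self):
        return [
            ConsensusDomain(interval=GenomicInterval("chr1", 1_000_000, 2_000_000),
                            boundary_score=1.0, condition="sham", support=3),
            ConsensusDomain(interval=GenomicInterval("chr1", 2_600_000, 3_000_000),
                            boundary_score=1.0, condition="sham", support=3),
        ]

    def test_inside(self):
        assert loop_tad_context(rloop(1_100_000, 1_800_000), self._tads()) == "inside"

    def test_inter_tad(self):
        assert loop_tad_context(rloop(1_500_000, 2_700_000), self._tads()) == "inter_tad"

    def test_one_anchor(self):
        assert loop_tad_context(rloop(1_500_000, 2_300_000), self._tads()) == "one_anchor"

    def test_outside(self):
        assert loop_tad_context(rloop(4_000_000, 4_500_000), self._tads()) == "outside"

    def test_three_way_mapping(self):
        assert context_three_way("inside") == "inside"
        assert context_three_way("outside") == "outside"
        assert context_three_way("one_anchor") == "cross_boundary"
        assert context_three_way("inter_tad") == "cross_boundary"

    def test_contexts_partition(self, pipeline_run):
        _, out_dir, _ = pipeline_run
        import pandas as pd

        df = pd.read_csv(out_dir / "loops_status.tsv", sep="\t")
        for cond in ("sham", "rep_6h", "rep_24h"):
            assert set(df[f"context_{cond}"]) <= {"inside", "outside", "one_anchor", "inter_tad"}


class TestAnchorDensity:
    def test_element_on_both_anchors_counted_twice(self):
        from hicrewire.loops import anchor_element_density

        lp = rloop(2_000_000, 2_005_000 + 10_000)  # anchors 5 kb apart... keep overlap simple
        # element spanning both 10 kb anchors of a very short loop
        elem = RegulatoryElement(
            interval=GenomicInterval("chr1", 2_000_000, 2_030_000), element_class="enhancer"
        )
        (row,) = anchor_element_density([lp], [elem])
        assert row["count_enhancer_anchor1"] == 1
        assert row["count_enhancer_anchor2"] == 1
        assert row["density_enhancer_anchor1"] == pytest.approx(0.1)

    def test_no_elements_zero(self):
        from hicrewire.loops import anchor_element_density

        (row,) = anchor_element_density([rloop(2_000_000, 5_000_000)], [])
        assert row["count_enhancer_anchor1"] == 0 and row["density_ctcf_anchor2"] == 0.0

    def test_three_enhancers_density(self):
        from hicrewire.loops import anchor_element_density

        elems = [
            RegulatoryElement(interval=GenomicInterval("chr1", 2_001_000 + i * 2_000, 2_001_500 + i * 2_000),
                              element_class="enhancer")
            for i in range(3)
        ]
        (row,) = anchor_element_density([rloop(2_000_000, 5_000_000)], elems)
        assert row["count_enhancer_anchor1"] == 3
        assert row["density_enhancer_anchor1"] == pytest.approx(0.3)
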
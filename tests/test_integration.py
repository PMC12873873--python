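"""Fisher exact test with Woolf CI, BH-FDR, Wilcoxon, transcript assignment,
enrichment direction convention, and flow tables."""

import math
from fractions import Fraction

import numpy as np
import pytest

from hicrewire.compartments import classify_switches
from hicrewire.domains import ConsensusDomain, DomainStatus
from hicrewire.integration import (
    AnnotatedTranscript,
    ContingencyTable,
    assign_transcripts,
    bh_adjust,
    enrichment_tables,
    fisher_enrichment,
    fisher_exact_pvalue,
    gained_lost_odds,
    sankey_flows,
    wilcoxon_rank_sum,
)
from hicrewire.intervals import GenomicInterval
from hicrewire.io import TranscriptRecord
from hicrewire.loops import LoopDelta


def enumeration_oracle(a, b, c, d):
    """Exact two-sided Fisher p as a Fraction, by full enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    probs = {}
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[k] = Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k),
                            math.comb(n, row1))
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


class TestFisher:
    def test_cross_product_or(self):
        r = fisher_enrichment(ContingencyTable(10, 10, 10, 30))
        assert r.odds_ratio == pytest.approx(3.0)

    def test_zero_cell_haldane_correction(self):
        r = fisher_enrichment(ContingencyTable(0, 10, 5, 20))
        # corrected cells (0.5, 10.5, 5.5, 20.5)
        assert r.odds_ratio == pytest.approx((0.5 * 20.5) / (10.5 * 5.5))
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_woolf_ci_form(self):
        r = fisher_enrichment(ContingencyTable(20, 10, 10, 20))
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert r.ci_low == pytest.approx(math.exp(math.log(4.0) - 1.96 * se))
        assert r.ci_high == pytest.approx(math.exp(math.log(4.0) + 1.96 * se))

    def test_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            a, b, c, d = (int(rng.integers(0, 41)) for _ in range(4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_pvalue(ContingencyTable(a, b, c, d))
            assert abs(p - float(enumeration_oracle(a, b, c, d))) < 1e-12

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact

        for table in [(10, 10, 10, 30), (3, 7, 12, 2), (0, 5, 8, 9), (15, 1, 2, 20)]:
            p = fisher_exact_pvalue(ContingencyTable(*table))
            _, p_ref = fisher_exact([[table[0], table[1]], [table[2], table[3]]])
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_pvalue(ContingencyTable(0, 0, 0, 0))

    def test_gained_lost_odds(self):
        r = gained_lost_odds(20, 10, 10, 20)
        assert r.odds_ratio == pytest.approx(4.0)
        assert gained_lost_odds(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_and_permutation_consistent(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            adj = np.array(bh_adjust(p))
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p
            perm = rng.permutation(len(p))
            adj_perm = np.array(bh_adjust(p[perm]))
            assert np.allclose(adj_perm, adj[perm])


class TestWilcoxon:
    def test_identical_samples_central(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_extreme_three_vs_three_exact(self):
        # most extreme allocation among C(6,3)=20: two-sided exact p = 2/20
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)

    def test_large_sample_asymptotic_matches_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)
        u, p = wilcoxon_rank_sum(x, y)
        # independent normal approximation with continuity correction (no ties)
        n1, n2 = 30, 30
        mu = n1 * n2 / 2
        sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (abs(u - mu) - 0.5) / sd
        assert p == pytest.approx(2 * (1 - 0.5 * (1 + math.erf(z / math.sqrt(2)))), abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


MB = 1_000_000


def _tx(tid, start, end, direction="up", biotype="coding"):
    return TranscriptRecord(
        transcript_id=tid, locus=GenomicInterval("chr1", start, end), biotype=biotype,
        log2_fc=2.0 if direction == "up" else (-2.0 if direction == "down" else 0.0),
        adj_p=0.01 if direction != "ns" else 0.9, direction=direction,
    )


def _delta(a1, a2, status):
    return LoopDelta(
        key=("chr1", a1, a1 + 10_000, a2, a2 + 10_000),
        in_sham=status in ("lost", "stable"), in_6h=status in ("gained_6h", "stable"),
        in_24h=False, status=status, lost_6h=False, lost_24h=False,
    )


def _tad(start, end, status):
    dom = ConsensusDomain(interval=GenomicInterval("chr1", start, end),
                          boundary_score=1.0, condition="rep_6h", support=3)
    return DomainStatus(domain=dom, status=status)


class TestAssignment:
    def _classes(self):
        ivs = [GenomicInterval("chr1", i * MB, (i + 1) * MB) for i in range(6)]
        sham = dict.fromkeys(ivs, "A")
        cond = dict.fromkeys(ivs, "A")
        return classify_switches(sham, cond, "rep_6h")

    def test_anchor_overlap_and_midpoint_memberships(self):
        deltas = [_delta(2 * MB, 3 * MB, "gained_6h")]
        tads = [_tad(1_500_000, 2_500_000, "lost")]
        tx = _tx("T1", 3 * MB + 2_000, 3 * MB + 4_000)  # overlaps anchor 2
        (ann,) = assign_transcripts([tx], deltas, tads, self._classes(), "rep_6h")
        assert ann.loop_statuses == ["gained_6h"]
        assert ann.tad_status is None  # midpoint outside the domain
        assert ann.compartment_class == "StableA"

    def test_multiple_memberships_recorded_with_precedence(self):
        deltas = [_delta(2 * MB, 3 * MB, "gained_6h"), _delta(2 * MB + 5_000, 4 * MB, "lost")]
        tx = _tx("T1", 2 * MB + 6_000, 2 * MB + 8_000)  # inside both anchor windows
        (ann,) = assign_transcripts([tx], deltas, [], self._classes(), "rep_6h")
        assert sorted(ann.loop_statuses) == ["gained_6h", "lost"]
        assert ann.flow_loop_status == "gained"  # precedence: gained > lost

    def test_tad_membership_by_midpoint(self):
        tads = [_tad(1_500_000, 2_500_000, "gained")]
        tx = _tx("T1", 2_400_000, 2_600_000)  # midpoint 2.5 Mb: half-open, outside
        (ann,) = assign_transcripts([tx], [], tads, self._classes(), "rep_6h")
        assert ann.tad_status is None
        tx2 = _tx("T2", 2_300_000, 2_500_000)
        (ann2,) = assign_transcripts([tx2], [], tads, self._classes(), "rep_6h")
        assert ann2.tad_status == "gained"


class TestEnrichmentTables:
    def _annotated(self):
        out = []
        # 10 up-coding in "gained" loops, 10 ns-coding mostly outside
        for i in range(10):
            out.append(AnnotatedTranscript(record=_tx(f"U{i}", MB, MB + 1000),
                                           loop_statuses=["gained_6h"]))
        for i in range(10):
            out.append(AnnotatedTranscript(
                record=_tx(f"N{i}", MB, MB + 1000, direction="ns"),
                loop_statuses=["lost"] if i < 2 else ["stable"]))
        return out

    def test_direction_convention_or_above_one(self):
        results = enrichment_tables(self._annotated(), layer="loop")
        by = {r.stratum: r for r in results}
        r = by["up:coding:gained"]
        # all 10 in-class transcripts sit in gained loops: strong over-representation
        assert r.table.a == 10 and r.odds_ratio > 1
        assert r.adj_p is not None and r.adj_p >= r.p

    def test_universe_modes(self):
        ann = self._annotated()
        ann.append(AnnotatedTranscript(record=_tx("X", MB, MB + 1000)))  # no membership
        located = enrichment_tables(ann, layer="loop", universe="all_located")
        expressed = enrichment_tables(ann, layer="loop", universe="all_expressed")
        n_located = located[0].table.n
        n_expressed = expressed[0].table.n
        assert n_expressed == n_located + 1


class TestFlows:
    def test_single_path_hundred_percent(self):
        anns = []
        for i in range(10):
            a = AnnotatedTranscript(record=_tx(f"T{i}", MB, MB + 1000),
                                    loop_statuses=["gained_6h"], tad_status="gained")
            a.compartment_class = "StableA"
            anns.append(a)
        flows = sankey_flows(anns)
        assert len(flows) == 1
        assert flows[0].path == "gained_loop>gained_tad>StableA"
        assert flows[0].percent_of_stratum == pytest.approx(100.0)

    def test_percent_sums_per_stratum(self, pipeline_run):
        results, _, _ = pipeline_run
        for tp in ("rep_6h", "rep_24h"):
            sums = {}
            for f in results.flows[tp]:
                sums[f.stratum] = sums.get(f.stratum, 0.0) + f.percent_of_stratum
            assert sums, "no flow strata computed"
            for total in sums.values():
                assert total == pytest.approx(100.0, abs=1e-9)

    def test_incomplete_paths_excluded(self):
        a = AnnotatedTranscript(record=_tx("T", MB, MB + 1000),
                                loop_statuses=["stable"], tad_status="gained")
        a.compartment_class = "StableA"
        assert sankey_flows([a]) == []
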
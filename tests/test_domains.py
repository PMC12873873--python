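"""TAD reproducibility, sham comparison, fusion/fission, strata, densities."""

from collections import Counter

import pytest

from hicrewire.domains import (
    ConsensusDomain,
    compare_to_sham,
    consensus_domains,
    detect_fusion_fission,
    domain_element_density,
    length_class,
    strength_class,
    stratify_domains,
)
from hicrewire.intervals import GenomicInterval
from hicrewire.io import DomainCall, RegulatoryElement


def call(start, end, score=1.5, rep=1, chrom="chr1"):
    return DomainCall(interval=GenomicInterval(chrom, start, end), boundary_score=score,
                      sample_id=f"rep{rep}", condition="sham", replicate=rep)


def cons(start, end, score=1.5, chrom="chr1", condition="rep_6h"):
    return ConsensusDomain(interval=GenomicInterval(chrom, start, end),
                           boundary_score=score, condition=condition, support=3)


class TestConsensus:
    def test_identical_replicates(self):
        reps = [[call(1_000_000, 1_500_000, rep=r)] for r in (1, 2, 3)]
        out = consensus_domains(reps)
        assert len(out) == 1 and out[0].support == 3
        assert out[0].interval == GenomicInterval("chr1", 1_000_000, 1_500_000)

    @pytest.mark.parametrize(
        "offset,reproducible",
        [(25_000, False), (20_000, True), (20_001, False), (15_000, True)],
    )
    def test_tolerance_boundary(self, offset, reproducible):
        reps = [
            [call(1_000_000, 1_500_000, rep=1)],
            [call(1_000_000 + offset, 1_500_000, rep=2)],
            [call(1_000_000, 1_500_000, rep=3)],
        ]
        assert (len(consensus_domains(reps)) == 1) is reproducible

    def test_both_ends_within_tolerance(self):
        reps = [
            [call(1_000_000, 1_500_000, rep=1)],
            [call(1_015_000, 1_518_000, rep=2)],  # (15 kb, 18 kb): both within 20 kb
            [call(1_000_000, 1_500_000, rep=3)],
        ]
        assert len(consensus_domains(reps)) == 1

    def test_reference_coordinates_and_mean_score(self):
        reps = [
            [call(1_000_000, 1_500_000, score=1.0, rep=1)],
            [call(1_010_000, 1_490_000, score=2.0, rep=2)],
            [call(995_000, 1_505_000, score=3.0, rep=3)],
        ]
        (d,) = consensus_domains(reps)
        assert d.interval.start == 1_000_000  # replicate 1 carries the coordinates
        assert d.boundary_score == pytest.approx(2.0)

    def test_replicate_domain_matched_at_most_once(self):
        # two reference domains cannot both claim one replicate-2 domain
        reps = [
            [call(1_000_000, 1_500_000, rep=1), call(1_010_000, 1_510_000, rep=1)],
            [call(1_000_000, 1_500_000, rep=2)],
        ]
        assert len(consensus_domains(reps)) == 1


class TestCompareToSham:
    def test_stable_small_displacement(self):
        sham = [cons(1_000_000, 1_500_000, condition="sham")]
        cond = [cons(1_005_000, 1_495_000)]
        (st,) = compare_to_sham(sham, cond)
        assert st.status == "stable" and st.partner == sham[0].interval

    def test_shifted_over_10kb(self):
        sham = [cons(1_000_000, 1_500_000, condition="sham")]
        cond = [cons(1_020_000, 1_500_000)]
        (st,) = compare_to_sham(sham, cond)
        assert st.status == "shifted"

    def test_low_ro_gained_and_lost(self):
        sham = [cons(1_000_000, 2_000_000, condition="sham")]
        cond = [cons(1_000_000, 1_300_000)]  # min RO = 0.3
        statuses = compare_to_sham(sham, cond)
        assert Counter(s.status for s in statuses) == {"gained": 1, "lost": 1}

    def test_partition_and_conservation(self, pipeline_run):
        results, _, _ = pipeline_run
        for tp in ("rep_6h", "rep_24h"):
            statuses = results.domain_statuses[tp]
            counts = Counter(s.status for s in statuses)
            n_cond = len(results.consensus_domains[tp])
            n_sham = len(results.consensus_domains["sham"])
            assert counts["stable"] + counts["shifted"] + counts["gained"] == n_cond
            assert counts["stable"] + counts["shifted"] + counts["lost"] == n_sham

    def test_permutation_stable(self):
        sham = [cons(1_000_000, 1_500_000, condition="sham"), cons(2_000_000, 2_400_000, condition="sham")]
        cond = [cons(2_000_000, 2_400_000), cons(1_005_000, 1_500_000)]
        a = compare_to_sham(sham, cond)
        b = compare_to_sham(sham[::-1], cond[::-1])
        key = lambda s: (s.domain.interval.start, s.status)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestFusionFission:
    def test_merged(self):
        sham = [cons(1_000_000, 1_400_000, condition="sham"), cons(1_450_000, 2_000_000, condition="sham")]
        cond = [cons(1_000_000, 2_000_000)]
        statuses = compare_to_sham(sham, cond)
        statuses = detect_fusion_fission(sham, cond, statuses)
        by_status = {s.status: s for s in statuses}
        assert by_status["gained"].category2 == "merged"
        assert all(s.category2 == "none" for s in statuses if s.status == "lost")

    def test_split_marks_parent_and_children(self):
        sham = [cons(1_000_000, 2_000_000, condition="sham")]
        cond = [cons(1_000_000, 1_400_000), cons(1_450_000, 2_000_000)]
        statuses = detect_fusion_fission(sham, cond, compare_to_sham(sham, cond))
        lost = [s for s in statuses if s.status == "lost"]
        gained = [s for s in statuses if s.status == "gained"]
        assert len(lost) == 1 and lost[0].category2 == "split"
        assert len(gained) == 2 and all(g.derived_from_split for g in gained)
        assert all(g.category2 == "none" for g in gained)

    def test_only_gained_lost_eligible(self):
        # a stable domain near two sham domains never gets a category2 label
        sham = [cons(1_000_000, 1_500_000, condition="sham"), cons(1_530_000, 1_900_000, condition="sham")]
        cond = [cons(1_000_000, 1_500_000), cons(1_530_000, 1_900_000)]
        statuses = detect_fusion_fission(sham, cond, compare_to_sham(sham, cond))
        assert all(s.category2 == "none" for s in statuses)
        assert all(s.status == "stable" for s in statuses)

    def test_status_never_altered(self):
        sham = [cons(1_000_000, 1_400_000, condition="sham"), cons(1_450_000, 2_000_000, condition="sham")]
        cond = [cons(1_000_000, 2_000_000)]
        before = compare_to_sham(sham, cond)
        after = detect_fusion_fission(sham, cond, before)
        assert [s.status for s in after] == [s.status for s in before]


class TestStrata:
    @pytest.mark.parametrize(
        "length,expected",
        [(250_000, "100to400kb"), (99_999, "lt100kb"), (100_000, "100to400kb"),
         (399_999, "100to400kb"), (400_000, "gt400kb")],
    )
    def test_length_class(self, length, expected):
        assert length_class(length) == expected

    @pytest.mark.parametrize("score,expected", [(1.0, "weak"), (2.3, "strong"), (0.99, "weak")])
    def test_strength_class_strictly_above_one(self, score, expected):
        assert strength_class(score) == expected

    def test_stratify_attaches_classes(self):
        sham = [cons(1_000_000, 1_250_000, score=1.0, condition="sham")]
        statuses = stratify_domains(compare_to_sham(sham, [cons(1_000_000, 1_250_000, score=1.0)]))
        st = [s for s in statuses if s.status != "lost"][0]
        assert st.length_class == "100to400kb" and st.strength_class == "weak"


class TestElementDensity:
    def test_counts_and_density(self):
        domain = cons(1_000_000, 1_500_000)
        elems = [
            RegulatoryElement(interval=GenomicInterval("chr1", 1_100_000 + i * 10_000, 1_101_000 + i * 10_000),
                              element_class="enhancer")
            for i in range(5)
        ]
        (row,) = domain_element_density([domain], elems)
        assert row["count_enhancer"] == 5
        assert row["density_enhancer"] == pytest.approx(5 / 500.0)
        assert row["count_promoter"] == 0

    def test_straddling_element_counted(self):
        domain = cons(1_000_000, 1_500_000)
        elem = RegulatoryElement(interval=GenomicInterval("chr1", 999_500, 1_000_500),
                                 element_class="ctcf")
        (row,) = domain_element_density([domain], [elem])
        assert row["count_ctcf"] == 1
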
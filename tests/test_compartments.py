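"""Compartment harmonization: z-scoring, orientation, consensus, switch classes."""

import math

import numpy as np
import pytest

from hicrewire.compartments import (
    CompartmentBin,
    assign_transcripts_to_compartments,
    class_fractions,
    classify_switches,
    condition_consensus,
    orient_labels,
    zscore_track,
)
from hicrewire.intervals import GenomicInterval
from hicrewire.io import EigenvectorTrack, TranscriptRecord

MB = 1_000_000


def track_from(values, chrom="chr1", sample_id="s"):
    bins = [
        (GenomicInterval(chrom, i * MB, (i + 1) * MB), float(v)) for i, v in enumerate(values)
    ]
    return EigenvectorTrack(bins=bins, bin_size=MB, sample_id=sample_id,
                            condition="sham", replicate=1)


class TestZScore:
    def test_two_bins_hand_computed(self):
        z = zscore_track(track_from([1.0, -1.0]))
        # sample SD of (1, -1) is sqrt(2): z = (+-1)/sqrt(2)
        assert z.values() == pytest.approx([1 / math.sqrt(2), -1 / math.sqrt(2)])

    def test_constant_track_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_track(track_from([0.4] * 10))

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        z = np.array(zscore_track(track_from(rng.normal(3, 2, size=40))).values())
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12


class TestOrientation:
    def _density(self, values):
        return track_from(values, sample_id="gene_density")

    def test_positive_correlation_no_flip(self):
        e = track_from([1.0, -0.5, 2.0, -1.5])
        d = self._density([10.0, 2.0, 14.0, 1.0])
        labels = [b.label for b in orient_labels(e, d)]
        assert labels == ["A", "B", "A", "B"]

    def test_sign_flip_invariance(self):
        d = self._density([10.0, 2.0, 14.0, 1.0])
        e = track_from([1.0, -0.5, 2.0, -1.5])
        e_neg = track_from([-1.0, 0.5, -2.0, 1.5])
        assert [b.label for b in orient_labels(e, d)] == [
            b.label for b in orient_labels(e_neg, d)
        ]

    def test_flip_invariance_random(self):
        # per-chromosome PC1 sign is arbitrary: orientation must undo any flip
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 1, size=12)
            vals[np.abs(vals) < 0.05] += 0.1  # keep labels unambiguous
            d = self._density(np.abs(vals) * np.sign(vals) * 2 + 5)
            a = [b.label for b in orient_labels(track_from(vals), d)]
            b = [b.label for b in orient_labels(track_from(-vals), d)]
            assert a == b

    def test_zero_correlation_rejected(self):
        e = track_from([1.0, -1.0, 1.0, -1.0])
        d = self._density([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            orient_labels(e, d)

    def test_missing_density_bins_rejected(self):
        e = track_from([1.0, -1.0, 2.0])
        d = self._density([5.0, 1.0])
        with pytest.raises(ValueError, match="cover"):
            orient_labels(e, d)


def bins_with_labels(labels, chrom="chr1"):
    return [
        CompartmentBin(
            interval=GenomicInterval(chrom, i * MB, (i + 1) * MB),
            z_eigen=1.0 if lab == "A" else -1.0,
            label=lab,
        )
        for i, lab in enumerate(labels)
    ]


class TestConsensusAndSwitches:
    def test_majority_vote(self):
        reps = [bins_with_labels(["A"]), bins_with_labels(["A"]), bins_with_labels(["B"])]
        (label,) = condition_consensus(reps).values()
        assert label == "A"

    def test_tie_unassigned(self):
        reps = [bins_with_labels(["A"]), bins_with_labels(["B"])]
        (label,) = condition_consensus(reps).values()
        assert label is None

    def test_unanimous(self):
        reps = [bins_with_labels(["B"])] * 3
        (label,) = condition_consensus(reps).values()
        assert label == "B"

    def test_inconsistent_binning_rejected(self):
        with pytest.raises(ValueError, match="binning"):
            condition_consensus([bins_with_labels(["A", "B"]), bins_with_labels(["A"])])

    def test_switch_table(self):
        ivs = [GenomicInterval("chr1", i * MB, (i + 1) * MB) for i in range(4)]
        sham = dict(zip(ivs, ["A", "B", "A", "B"]))
        cond = dict(zip(ivs, ["B", "B", "A", "A"]))
        classes = classify_switches(sham, cond, "rep_6h")
        assert [c.switch_class for c in classes] == ["AtoB", "StableB", "StableA", "BtoA"]
        fracs = class_fractions(classes)
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_unassigned_bins_dropped(self):
        ivs = [GenomicInterval("chr1", i * MB, (i + 1) * MB) for i in range(2)]
        sham = dict(zip(ivs, ["A", None]))
        cond = dict(zip(ivs, ["B", "A"]))
        classes = classify_switches(sham, cond, "rep_6h")
        assert len(classes) == 1 and classes[0].switch_class == "AtoB"


class TestTranscriptAssignment:
    def _classes(self):
        ivs = [GenomicInterval("chr1", i * MB, (i + 1) * MB) for i in range(2)]
        sham = dict(zip(ivs, ["A", "B"]))
        cond = dict(zip(ivs, ["B", "B"]))
        return classify_switches(sham, cond, "rep_6h")

    def _tx(self, tid, chrom, start, end):
        return TranscriptRecord(transcript_id=tid,
                                locus=GenomicInterval(chrom, start, end),
                                biotype="coding", log2_fc=0.0, adj_p=1.0, direction="ns")

    def test_midpoint_bin(self):
        classes = self._classes()
        tx = self._tx("T1", "chr1", 100_000, 200_000)
        assert assign_transcripts_to_compartments([tx], classes)["T1"] == "AtoB"

    def test_absent_chromosome_none(self):
        classes = self._classes()
        tx = self._tx("T2", "chrX", 0, 1000)
        assert assign_transcripts_to_compartments([tx], classes)["T2"] is None

    def test_spanning_transcript_uses_midpoint(self):
        classes = self._classes()
        # locus spans both bins; midpoint at 1.1 Mb falls in the StableB bin
        tx = self._tx("T3", "chr1", 700_000, 1_500_000)
        assert assign_transcripts_to_compartments([tx], classes)["T3"] == "StableB"
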
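"""A/B compartment harmonization and switch classification at 1 Mb bins.

Pipeline order per sample: genome-wide z-scoring of the raw eigenvector,
then per-chromosome sign orientation against gene density (PC1 sign is
arbitrary per chromosome; bins positively correlated with gene density are
compartment A).  Replicate labels are merged by majority vote into a
per-condition consensus, and each bin's switch class relative to sham is one
of StableA / StableB / AtoB / BtoA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import EigenvectorTrack, TranscriptRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentBin",
    "CompartmentClass",
    "SWITCH_CLASSES",
    "zscore_track",
    "orient_labels",
    "condition_consensus",
    "classify_switches",
    "class_fractions",
    "assign_transcripts_to_compartments",
]

SWITCH_CLASSES = ("StableA", "StableB", "AtoB", "BtoA")


@dataclass(frozen=True)
class CompartmentBin:
    """One 1 Mb bin with its oriented, z-scored eigenvalue and A/B label.

    ``label`` is ``None`` for bins whose oriented value is exactly 0 (no
    defensible A/B call).
    """

    interval: GenomicInterval
    z_eigen: float
    label: str | None


@dataclass(frozen=True)
class CompartmentClass:
    interval: GenomicInterval
    sham_label: str
    condition_label: str
    switch_class: str
    timepoint: str


def zscore_track(track: EigenvectorTrack) -> EigenvectorTrack:
    """Genome-wide per-sample z-score (mean 0, sample SD 1 over retained bins)."""
    values = np.asarray(track.values(), dtype=float)
    if values.size < 2:
        raise ValueError("zscore_track requires >= 2 bins")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"sample {track.sample_id}: zero-variance eigenvector track")
    z = (values - values.mean()) / sd
    return EigenvectorTrack(
        bins=[(iv, float(v)) for (iv, _), v in zip(track.bins, z)],
        bin_size=track.bin_size,
        sample_id=track.sample_id,
        condition=track.condition,
        replicate=track.replicate,
    )


def orient_labels(
    track: EigenvectorTrack, gene_density: EigenvectorTrack
) -> list[CompartmentBin]:
    """Orient eigenvalue signs per chromosome against gene density, then label.

    If the Pearson correlation between a chromosome's eigenvalues and gene
    density is negative, that chromosome's signs are flipped; afterwards,
    bins with positive values are labeled A, negative B.  A correlation of
    exactly zero (or undefined, e.g. constant density) is an error — the
    orientation would be arbitrary.
    """
    density_by_bin = {iv: v for iv, v in gene_density.bins}
    missing = [iv for iv, _ in track.bins if iv not in density_by_bin]
    if missing:
        raise ValueError(
            f"gene-density track does not cover {len(missing)} bin(s), e.g. {missing[0]}"
        )
    by_chrom: dict[str, list[tuple[GenomicInterval, float]]] = {}
    for iv, v in track.bins:
        by_chrom.setdefault(iv.chrom, []).append((iv, v))
    out: list[CompartmentBin] = []
    for chrom in sorted(by_chrom):
        chrom_bins = by_chrom[chrom]
        e = np.array([v for _, v in chrom_bins])
        d = np.array([density_by_bin[iv] for iv, _ in chrom_bins])
        if e.size < 2 or np.std(e) == 0 or np.std(d) == 0:
            raise ValueError(f"{chrom}: orientation undefined (degenerate track)")
        r = float(np.corrcoef(e, d)[0, 1])
        if r == 0 or math.isnan(r):
            raise ValueError(f"{chrom}: ambiguous orientation (correlation {r})")
        sign = -1.0 if r < 0 else 1.0
        for iv, v in chrom_bins:
            val = sign * v
            label = "A" if val > 0 else ("B" if val < 0 else None)
            out.append(CompartmentBin(interval=iv, z_eigen=val, label=label))
    out.sort(key=lambda b: (b.interval.chrom, b.interval.start))
    return out


def condition_consensus(
    replicate_bins: Sequence[Sequence[CompartmentBin]],
) -> dict[GenomicInterval, str | None]:
    """Majority-vote A/B label per bin across replicates; ties -> None.

    Bins without a strict majority are marked unassigned (``None``) and are
    excluded from switch classification downstream.
    """
    if not replicate_bins:
        raise ValueError("need >= 1 replicate")
    binning = [b.interval for b in replicate_bins[0]]
    for rep in replicate_bins[1:]:
        if [b.interval for b in rep] != binning:
            raise ValueError("replicates have inconsistent binning")
    consensus: dict[GenomicInterval, str | None] = {}
    n_tied = 0
    for bins_at in zip(*replicate_bins):
        iv = bins_at[0].interval
        votes_a = sum(1 for b in bins_at if b.label == "A")
        votes_b = sum(1 for b in bins_at if b.label == "B")
        if votes_a > votes_b:
            consensus[iv] = "A"
        elif votes_b > votes_a:
            consensus[iv] = "B"
        else:
            consensus[iv] = None
            n_tied += 1
    if n_tied:
        logger.info("condition consensus: %d bin(s) unassigned (no strict majority)", n_tied)
    return consensus


def classify_switches(
    sham_labels: Mapping[GenomicInterval, str | None],
    condition_labels: Mapping[GenomicInterval, str | None],
    timepoint: str,
) -> list[CompartmentClass]:
    """Classify each bin relative to sham: StableA/StableB/AtoB/BtoA.

    Bins unassigned on either side are dropped; the class is a pure function
    of (sham label, condition label).
    """
    table = {("A", "A"): "StableA", ("B", "B"): "StableB", ("A", "B"): "AtoB", ("B", "A"): "BtoA"}
    out: list[CompartmentClass] = []
    for iv in sorted(set(sham_labels) & set(condition_labels), key=lambda iv: (iv.chrom, iv.start)):
        s, c = sham_labels[iv], condition_labels[iv]
        if s is None or c is None:
            continue
        out.append(
            CompartmentClass(
                interval=iv, sham_label=s, condition_label=c,
                switch_class=table[(s, c)], timepoint=timepoint,
            )
        )
    return out


def class_fractions(classes: Sequence[CompartmentClass]) -> dict[str, float]:
    """Fraction of classified bins in each switch class (sums to 1)."""
    if not classes:
        return {k: 0.0 for k in SWITCH_CLASSES}
    n = len(classes)
    return {k: sum(1 for c in classes if c.switch_class == k) / n for k in SWITCH_CLASSES}


def assign_transcripts_to_compartments(
    transcripts: Sequence[TranscriptRecord],
    classes: Sequence[CompartmentClass],
) -> dict[str, str | None]:
    """Map transcript id -> switch class of the bin containing its locus midpoint.

    Transcripts whose midpoint falls in an unassigned or blacklisted bin (or
    on a chromosome absent from the binning) map to ``None``.
    """
    by_chrom: dict[str, list[CompartmentClass]] = {}
    for c in classes:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for lst in by_chrom.values():
        lst.sort(key=lambda c: c.interval.start)
    out: dict[str, str | None] = {}
    for t in transcripts:
        mid = t.locus.midpoint
        assigned = None
        for c in by_chrom.get(t.locus.chrom, ()):  # 1 Mb bins: linear scan is fine
            if c.interval.contains_point(mid):
                assigned = c.switch_class
                break
        out[t.transcript_id] = assigned
    return out
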
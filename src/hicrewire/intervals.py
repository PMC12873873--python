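"""Genomic interval arithmetic and overlap primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Every downstream comparison (reciprocal overlap of TADs, boundary displacement,
blacklist removal, element counting at loop anchors) reduces to the handful of
primitives defined here, so they are kept deliberately small and exhaustively
tested against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "OverlapPair",
    "overlap_length",
    "reciprocal_overlap",
    "boundary_displacement",
    "find_overlaps",
    "subtract_blacklist",
    "harmonize_chrom",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos: int) -> bool:
        """Half-open membership test for a single base position."""
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class OverlapPair:
    """One overlapping (query, subject) pair with reciprocal-overlap fractions."""

    query_index: int
    subject_index: int
    overlap_bp: int
    ro_query: float
    ro_subject: float


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval's own length.

    The reciprocal-overlap criterion ``RO >= t`` used for TAD matching is
    satisfied iff ``min(*reciprocal_overlap(a, b)) >= t``.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"reciprocal_overlap requires same chromosome ({a.chrom} vs {b.chrom})")
    ov = overlap_length(a, b)
    return ov / len(a), ov / len(b)


def boundary_displacement(a: GenomicInterval, b: GenomicInterval) -> tuple[int, int]:
    """Absolute displacement of the left and right boundaries, in bp."""
    if a.chrom != b.chrom:
        raise ValueError(f"boundary_displacement requires same chromosome ({a.chrom} vs {b.chrom})")
    return abs(a.start - b.start), abs(a.end - b.end)


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[OverlapPair]:
    """All (query, subject) pairs sharing >= 1 bp, each exactly once.

    Output is ordered by (query index, subject index). Per chromosome the
    subjects are sorted by start and candidates are pruned with a binary
    search on the start coordinate, which is ample for the feature-list
    sizes this pipeline handles (10^2–10^4 intervals).
    """
    if not query or not subject:
        return []
    by_chrom: dict[str, list[int]] = {}
    for j, s in enumerate(subject):
        by_chrom.setdefault(s.chrom, []).append(j)
    chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idx in by_chrom.items():
        starts = np.array([subject[j].start for j in idx], dtype=np.int64)
        ends = np.array([subject[j].end for j in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        chrom_arrays[chrom] = (starts[order], ends[order], np.array(idx)[order])

    pairs: list[OverlapPair] = []
    for i, q in enumerate(query):
        entry = chrom_arrays.get(q.chrom)
        if entry is None:
            continue
        starts, ends, idx = entry
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if hi == 0:
            continue
        cand = np.nonzero(ends[:hi] > q.start)[0]
        hits: list[tuple[int, int]] = []
        for k in cand:
            j = int(idx[k])
            ov = min(q.end, int(ends[k])) - max(q.start, int(starts[k]))
            hits.append((j, ov))
        for j, ov in sorted(hits):
            s = subject[j]
            pairs.append(
                OverlapPair(
                    query_index=i,
                    subject_index=j,
                    overlap_bp=ov,
                    ro_query=ov / len(q),
                    ro_subject=ov / len(s),
                )
            )
    return pairs


def subtract_blacklist(
    intervals: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every interval overlapping a blacklist region by >= 1 bp.

    Whole-record removal, never trimming: a bin grazing a centromere is
    excluded entirely, matching the conservative reading of "bins
    overlapping centromeres or telomeres were removed".
    """
    if not blacklist:
        return list(intervals)
    flagged = {p.query_index for p in find_overlaps(intervals, blacklist)}
    return [iv for i, iv in enumerate(intervals) if i not in flagged]


def harmonize_chrom(name: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Map a chromosome name through an alias table (e.g. ``"1" -> "chr1"``).

    With no alias map the name is returned stripped but otherwise untouched;
    comparisons everywhere downstream are string-exact.
    """
    name = name.strip()
    if alias_map and name in alias_map:
        return alias_map[name]
    return name


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Deterministic (chrom, start, end) ordering used by writers and matchers."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
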
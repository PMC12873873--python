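"""Readers and writers for the tabular formats the pipeline consumes.

Formats handled (all plain text, tab-separated, ``#`` comment lines allowed):

* eigenvector / gene-density tracks — 4-column bedGraph at 1 Mb bins;
* TAD domain lists — Arrowhead-style BEDPE-like tables with a boundary-score
  column (the mirrored ``chrom2/start2/end2`` triple is tolerated and checked);
* loop lists — HiCCUPS-style BEDPE plus per-context statistics, one
  observed / obs-over-exp / adjusted-p triple per local background context
  (BL, Donut, H, V);
* regulatory-element BED files (enhancer / promoter / CTCF site /
  super-enhancer / stroke-specific super-enhancer);
* transcript-level differential-expression tables.

Every reader validates, harmonizes chromosome names, applies the blacklist
and intra-chromosomal filters where the analysis demands them, and logs how
many records were dropped so that count conservation stays auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, harmonize_chrom, subtract_blacklist

logger = logging.getLogger(__name__)

__all__ = [
    "CONTEXTS",
    "ELEMENT_CLASSES",
    "CONDITIONS",
    "ContextStats",
    "EigenvectorTrack",
    "DomainCall",
    "LoopCall",
    "RegulatoryElement",
    "TranscriptRecord",
    "read_eigenvector_bedgraph",
    "write_eigenvector_bedgraph",
    "read_domain_list",
    "write_domain_list",
    "read_loop_list",
    "write_loop_list",
    "read_bed_elements",
    "write_bed_elements",
    "read_transcripts",
    "write_transcripts",
    "read_blacklist",
    "write_blacklist",
]

#: HiCCUPS local background contexts: bottom-left, donut, horizontal, vertical.
CONTEXTS = ("BL", "Donut", "H", "V")

ELEMENT_CLASSES = (
    "enhancer",
    "promoter",
    "ctcf",
    "super_enhancer",
    "stroke_super_enhancer",
)

#: Experimental conditions: sham surgery and 6 h / 24 h reperfusion after occlusion.
CONDITIONS = ("sham", "rep_6h", "rep_24h")

#: Default loop-table column names for the per-context statistics.  Dialects
#: vary across callers; pass a ``column_map`` to remap.
DEFAULT_LOOP_COLUMNS = {
    ("observed", c): f"obs_{c.lower()}" for c in CONTEXTS
} | {
    ("oe", c): f"oe_{c.lower()}" for c in CONTEXTS
} | {
    ("adj_p", c): f"fdr_{c.lower()}" for c in CONTEXTS
}


@dataclass(frozen=True)
class ContextStats:
    """Per-context loop statistics: observed counts, obs/exp ratio, adjusted p."""

    observed: float
    oe: float
    adj_p: float


@dataclass
class EigenvectorTrack:
    """An ordered 1 Mb-binned eigenvector (or gene-density) track for one sample."""

    bins: list[tuple[GenomicInterval, float]]
    bin_size: int
    sample_id: str
    condition: str
    replicate: int

    def values(self) -> list[float]:
        return [v for _, v in self.bins]

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.bins]


@dataclass(frozen=True)
class DomainCall:
    """One TAD call from one replicate, with its boundary z-score."""

    interval: GenomicInterval
    boundary_score: float
    sample_id: str
    condition: str
    replicate: int


@dataclass(frozen=True)
class LoopCall:
    """One intra-chromosomal loop call with per-context statistics.

    Anchors are canonically ordered (``anchor1.start <= anchor2.start``).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    stats: Mapping[str, ContextStats]
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0

    @property
    def key(self) -> tuple[str, int, int, int, int]:
        """Exact-coordinate identity used to compare loops across conditions."""
        return (
            self.anchor1.chrom,
            self.anchor1.start,
            self.anchor1.end,
            self.anchor2.start,
            self.anchor2.end,
        )

    @property
    def span(self) -> int:
        return self.anchor2.start - self.anchor1.start


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """A located transcript with its differential-expression call.

    ``direction`` is derived at load time from the sign of ``log2_fc`` and the
    adjusted-p / fold-change thresholds, never trusted from the file.
    """

    transcript_id: str
    locus: GenomicInterval
    biotype: str  # "coding" | "noncoding"
    log2_fc: float
    adj_p: float
    direction: str  # "up" | "down" | "ns"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _drop_blacklisted(intervals, records, blacklist, what: str):
    """Whole-record blacklist filter returning kept records + dropped count."""
    if not blacklist:
        return list(records), 0
    kept_ivs = set(subtract_blacklist(intervals, blacklist))
    kept = [r for iv, r in zip(intervals, records) if iv in kept_ivs]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("%s: dropped %d blacklist-overlapping record(s)", what, dropped)
    return kept, dropped


# ---------------------------------------------------------------------------
# eigenvector / bedGraph
# ---------------------------------------------------------------------------

def read_eigenvector_bedgraph(
    path: str | Path,
    *,
    sample_id: str = "",
    condition: str = "",
    replicate: int = 0,
    bin_size: int = 1_000_000,
    blacklist: Sequence[GenomicInterval] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> EigenvectorTrack:
    """Read a 4-column bedGraph into a sorted, validated track.

    Raises ``ValueError`` (naming the offending line/bin) for malformed lines,
    non-finite values, or overlapping bins.
    """
    path = Path(path)
    bins: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}")
            chrom, start_s, end_s, val_s = parts
            try:
                iv = GenomicInterval(harmonize_chrom(chrom, alias_map), int(start_s), int(end_s))
                value = float(val_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if value != value or value in (float("inf"), float("-inf")):
                raise ValueError(f"{path}:{lineno}: non-finite value in bin {iv}")
            bins.append((iv, value))
    bins.sort(key=lambda b: (b[0].chrom, b[0].start))
    prev: GenomicInterval | None = None
    for iv, _ in bins:
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise ValueError(f"{path}: overlapping bins {prev} and {iv}")
        prev = iv
    if blacklist:
        kept = set(subtract_blacklist([iv for iv, _ in bins], list(blacklist)))
        n0 = len(bins)
        bins = [(iv, v) for iv, v in bins if iv in kept]
        if len(bins) != n0:
            logger.info("%s: dropped %d blacklisted bin(s)", path, n0 - len(bins))
    return EigenvectorTrack(
        bins=bins, bin_size=bin_size, sample_id=sample_id, condition=condition, replicate=replicate
    )


def write_eigenvector_bedgraph(track: EigenvectorTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, v in track.bins:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# domain lists
# ---------------------------------------------------------------------------

def read_domain_list(
    path: str | Path,
    *,
    sample_id: str = "",
    condition: str = "",
    replicate: int = 0,
    score_column: str = "boundary_score",
    blacklist: Sequence[GenomicInterval] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[DomainCall]:
    """Read an Arrowhead-style domain table.

    A domain spans left-boundary start to right-boundary end.  Mirrored
    ``chrom2/start2/end2`` columns, if present, must agree (interchromosomal
    records are dropped and logged).  Records overlapping the blacklist are
    removed whole.
    """
    df = _read_table(path)
    if score_column not in df.columns:
        raise ValueError(f"{path}: missing score column {score_column!r}")
    n_inter = 0
    calls: list[DomainCall] = []
    for _, row in df.iterrows():
        chrom = harmonize_chrom(str(row["chrom"]), alias_map)
        if "chrom2" in df.columns and harmonize_chrom(str(row["chrom2"]), alias_map) != chrom:
            n_inter += 1
            continue
        iv = GenomicInterval(chrom, int(row["start"]), int(row["end"]))
        calls.append(
            DomainCall(
                interval=iv,
                boundary_score=float(row[score_column]),
                sample_id=sample_id,
                condition=condition,
                replicate=replicate,
            )
        )
    if n_inter:
        logger.info("%s: dropped %d interchromosomal domain record(s)", path, n_inter)
    calls, _ = _drop_blacklisted([c.interval for c in calls], calls, list(blacklist or []), str(path))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return calls


def write_domain_list(calls: Sequence[DomainCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tchrom2\tstart2\tend2\tboundary_score\n")
        for c in calls:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{c.boundary_score:.6g}\n"
            )


# ---------------------------------------------------------------------------
# loop lists
# ---------------------------------------------------------------------------

def read_loop_list(
    path: str | Path,
    *,
    sample_id: str = "",
    condition: str = "",
    replicate: int = 0,
    resolution: int = 10_000,
    column_map: Mapping[tuple[str, str], str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[LoopCall]:
    """Read a HiCCUPS-style loop table with per-context statistics.

    Interchromosomal pairs are excluded (logged); anchors are canonically
    ordered so ``anchor1.start <= anchor2.start``.  Anchors not matching the
    calling resolution trigger a warning, not an error — off-grid anchors can
    be legitimate at chromosome ends.
    """
    cmap = dict(DEFAULT_LOOP_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    for key, col in cmap.items():
        if col not in df.columns:
            raise ValueError(f"{path}: missing loop statistic column {col!r} for {key}")
    n_inter = 0
    loops: list[LoopCall] = []
    for idx, row in df.iterrows():
        c1 = harmonize_chrom(str(row["chrom1"]), alias_map)
        c2 = harmonize_chrom(str(row["chrom2"]), alias_map)
        if c1 != c2:
            n_inter += 1
            continue
        a1 = GenomicInterval(c1, int(row["start1"]), int(row["end1"]))
        a2 = GenomicInterval(c2, int(row["start2"]), int(row["end2"]))
        if a2.start < a1.start:
            a1, a2 = a2, a1
        for a in (a1, a2):
            if len(a) != resolution:
                logger.warning(
                    "%s: anchor %s width %d != calling resolution %d", path, a, len(a), resolution
                )
        stats = {}
        for ctx in CONTEXTS:
            try:
                stats[ctx] = ContextStats(
                    observed=float(row[cmap[("observed", ctx)]]),
                    oe=float(row[cmap[("oe", ctx)]]),
                    adj_p=float(row[cmap[("adj_p", ctx)]]),
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: row {idx}: unparseable statistic for context {ctx}") from exc
        loops.append(
            LoopCall(
                anchor1=a1, anchor2=a2, stats=stats,
                sample_id=sample_id, condition=condition, replicate=replicate,
            )
        )
    if n_inter:
        logger.info("%s: dropped %d interchromosomal loop(s)", path, n_inter)
    loops.sort(key=lambda l: l.key)
    return loops


def write_loop_list(loops: Sequence[LoopCall], path: str | Path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    stat_cols = [DEFAULT_LOOP_COLUMNS[(s, c)] for s in ("observed", "oe", "adj_p") for c in CONTEXTS]
    with open(path, "w") as fh:
        fh.write("\t".join(cols + stat_cols) + "\n")
        for lp in loops:
            vals = [
                lp.anchor1.chrom, str(lp.anchor1.start), str(lp.anchor1.end),
                lp.anchor2.chrom, str(lp.anchor2.start), str(lp.anchor2.end),
            ]
            for stat in ("observed", "oe", "adj_p"):
                for ctx in CONTEXTS:
                    vals.append(f"{getattr(lp.stats[ctx], stat):.6g}")
            fh.write("\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# regulatory elements / blacklist BED
# ---------------------------------------------------------------------------

def read_bed_elements(
    path: str | Path,
    element_class: str,
    *,
    alias_map: Mapping[str, str] | None = None,
) -> list[RegulatoryElement]:
    if element_class not in ELEMENT_CLASSES:
        raise ValueError(f"unknown element class {element_class!r}")
    out = []
    for iv in read_blacklist(path, alias_map=alias_map):
        out.append(RegulatoryElement(interval=iv, element_class=element_class))
    return out


def write_bed_elements(elements: Sequence[RegulatoryElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sorted(elements, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end)):
            iv = e.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.element_class}\n")


def read_blacklist(
    path: str | Path, *, alias_map: Mapping[str, str] | None = None
) -> list[GenomicInterval]:
    """Read a BED3(+) file as bare intervals (used for blacklists and elements)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            out.append(
                GenomicInterval(harmonize_chrom(parts[0], alias_map), int(parts[1]), int(parts[2]))
            )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_blacklist(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def read_transcripts(
    path: str | Path,
    *,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    alias_map: Mapping[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Read a transcript DE table and assign up/down/ns directions.

    A transcript is called differentially expressed iff ``adj_p < p_threshold``
    and ``|log2_fc| >= fc_threshold``; the direction is the sign of the fold
    change, otherwise ``ns``.
    """
    df = _read_table(path)
    required = {"transcript_id", "chrom", "start", "end", "biotype", "log2_fc", "adj_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing transcript columns {sorted(missing)}")
    out: list[TranscriptRecord] = []
    for _, row in df.iterrows():
        biotype = str(row["biotype"])
        if biotype not in ("coding", "noncoding"):
            raise ValueError(f"{path}: unknown biotype {biotype!r}")
        log2_fc = float(row["log2_fc"])
        adj_p = float(row["adj_p"])
        if adj_p < p_threshold and abs(log2_fc) >= fc_threshold:
            direction = "up" if log2_fc > 0 else "down"
        else:
            direction = "ns"
        out.append(
            TranscriptRecord(
                transcript_id=str(row["transcript_id"]),
                locus=GenomicInterval(
                    harmonize_chrom(str(row["chrom"]), alias_map), int(row["start"]), int(row["end"])
                ),
                biotype=biotype,
                log2_fc=log2_fc,
                adj_p=adj_p,
                direction=direction,
            )
        )
    out.sort(key=lambda t: t.transcript_id)
    return out


def write_transcripts(transcripts: Sequence[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstart\tend\tbiotype\tlog2_fc\tadj_p\n")
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            iv = t.locus
            fh.write(
                f"{t.transcript_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{t.biotype}\t"
                f"{t.log2_fc:.6g}\t{t.adj_p:.6g}\n"
            )
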
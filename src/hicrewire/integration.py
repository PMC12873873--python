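"""Integration of 3D architecture with transcript-level differential expression.

Transcripts are linked to loops (locus overlapping either anchor), TADs
(locus midpoint inside the domain) and compartment bins (midpoint bin), and
class enrichment within architectural strata is scored with two-sided
Fisher's exact tests: odds ratio with a Woolf (log-normal) 95% CI, BH-FDR
adjusted p-values within each family.  Distribution comparisons (boundary
strength, loop length, element density) use the Wilcoxon rank-sum test.
Hierarchical loop -> TAD -> compartment flow tables back Sankey-style
summaries of where regulated transcripts travel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .compartments import CompartmentClass, assign_transcripts_to_compartments
from .domains import DomainStatus
from .intervals import GenomicInterval, find_overlaps
from .io import TranscriptRecord
from .loops import LoopDelta

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "AnnotatedTranscript",
    "FlowRecord",
    "fisher_exact_pvalue",
    "fisher_enrichment",
    "bh_adjust",
    "gained_lost_odds",
    "wilcoxon_rank_sum",
    "assign_transcripts",
    "enrichment_tables",
    "sankey_flows",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (class & stratum, class & ~stratum, ~class & stratum, ~class & ~stratum)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    stratum: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    adj_p: float | None
    table: ContingencyTable


@dataclass
class AnnotatedTranscript:
    """A transcript with its architectural memberships at one timepoint."""

    record: TranscriptRecord
    loop_statuses: list[str] = field(default_factory=list)  # statuses of loops whose anchors it overlaps
    tad_status: str | None = None
    compartment_class: str | None = None

    @property
    def flow_loop_status(self) -> str | None:
        """Single loop status for flow analysis; gained takes precedence over lost."""
        present = set(self.loop_statuses)
        if any(s.startswith("gained") for s in present):
            return "gained"
        if "lost" in present:
            return "lost"
        if "stable" in present:
            return "stable"
        return None


@dataclass(frozen=True)
class FlowRecord:
    stratum: str  # e.g. "up:noncoding"
    path: str  # e.g. "gained_loop>gained_tad>StableA"
    count: int
    percent_of_stratum: float


# ---------------------------------------------------------------------------
# Fisher exact test with Woolf CI
# ---------------------------------------------------------------------------

def fisher_exact_pvalue(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p via exact integer hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's; the
    comparison is done on exact integer numerators, so ties are resolved
    exactly rather than to floating-point tolerance.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n < 1:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    # numerator of P(X = k) is comb(col1, k) * comb(n - col1, row1 - k)
    num_obs = comb(col1, a) * comb(n - col1, row1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num_k = comb(col1, k) * comb(n - col1, row1 - k)
        if num_k <= num_obs:
            total += num_k
    return float(total / comb(n, row1))


def fisher_enrichment(table: ContingencyTable, stratum: str = "") -> EnrichmentResult:
    """Two-sided Fisher p, sample odds ratio, and Woolf 95% CI.

    The OR is the cross-product (a·d)/(b·c); when any cell is zero the
    Haldane–Anscombe +0.5 correction is applied to every cell for both the
    OR and the CI.  The CI is exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))
    on the (corrected) cells.
    """
    p = fisher_exact_pvalue(table)
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    if 0 in cells:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_) - 1.96 * se)
    ci_high = math.exp(math.log(or_) + 1.96 * se)
    return EnrichmentResult(
        stratum=stratum, odds_ratio=or_, ci_low=ci_low, ci_high=ci_high,
        p=p, adj_p=None, table=table,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def gained_lost_odds(
    cond_gained: int, cond_lost: int, ref_gained: int, ref_lost: int, stratum: str = ""
) -> EnrichmentResult:
    """Odds ratio of gained:lost at a condition versus a reference stratum."""
    return fisher_enrichment(
        ContingencyTable(a=cond_gained, b=cond_lost, c=ref_gained, d=ref_lost),
        stratum=stratum,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration of the U distribution when the combined sample size is
    <= 12 with no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    combined = x + y
    exact = len(combined) <= 12 and len(set(combined)) == len(combined)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# transcript assignment
# ---------------------------------------------------------------------------

def assign_transcripts(
    transcripts: Sequence[TranscriptRecord],
    loop_deltas: Sequence[LoopDelta],
    tad_statuses: Sequence[DomainStatus],
    compartment_classes: Sequence[CompartmentClass],
    timepoint: str,
) -> list[AnnotatedTranscript]:
    """Attach loop / TAD / compartment memberships to every transcript.

    Loop membership: the transcript locus overlaps either anchor of a loop in
    the union set (all of that loop's statuses are recorded; multiple
    memberships are allowed).  TAD membership: locus midpoint inside a
    consensus domain (status record from this timepoint's comparison).
    Compartment: switch class of the midpoint bin.
    """
    annotated = [AnnotatedTranscript(record=t) for t in transcripts]
    loci = [t.locus for t in transcripts]

    # loops: overlap of locus with either anchor
    anchor_ivs: list[GenomicInterval] = []
    anchor_owner: list[int] = []
    for li, delta in enumerate(loop_deltas):
        chrom, s1, e1, s2, e2 = delta.key
        anchor_ivs.append(GenomicInterval(chrom, s1, e1))
        anchor_owner.append(li)
        anchor_ivs.append(GenomicInterval(chrom, s2, e2))
        anchor_owner.append(li)
    seen: set[tuple[int, int]] = set()
    for p in find_overlaps(loci, anchor_ivs):
        li = anchor_owner[p.subject_index]
        if (p.query_index, li) in seen:  # same loop via both anchors: record once
            continue
        seen.add((p.query_index, li))
        annotated[p.query_index].loop_statuses.append(loop_deltas[li].status)

    # TADs: midpoint containment (condition-side records only: stable/shifted/
    # gained from the condition set plus lost sham domains)
    for ann in annotated:
        mid = ann.record.locus.midpoint
        for st in tad_statuses:
            iv = st.domain.interval
            if iv.chrom == ann.record.locus.chrom and iv.contains_point(mid):
                ann.tad_status = st.status
                break

    comp = assign_transcripts_to_compartments(transcripts, compartment_classes)
    for ann in annotated:
        ann.compartment_class = comp.get(ann.record.transcript_id)
    logger.info(
        "%s: annotated %d transcripts (%d with loop membership, %d in TADs, %d in bins)",
        timepoint, len(annotated),
        sum(1 for a in annotated if a.loop_statuses),
        sum(1 for a in annotated if a.tad_status),
        sum(1 for a in annotated if a.compartment_class),
    )
    return annotated


def enrichment_tables(
    annotated: Sequence[AnnotatedTranscript],
    layer: str,
    universe: str = "all_located",
) -> list[EnrichmentResult]:
    """Fisher enrichment of transcript classes within one architecture layer.

    ``layer`` is one of ``loop``, ``tad``, ``compartment``.  For every
    (direction in {up, down}) x (biotype) transcript class and every stratum
    of the layer, a 2x2 table is built over the universe: ``all_located``
    restricts to transcripts with any membership in that layer,
    ``all_expressed`` uses every transcript.  Each transcript counts once per
    stratum (memberships deduplicated).  The whole layer is one BH family.
    """
    def strata_of(ann: AnnotatedTranscript) -> set[str]:
        if layer == "loop":
            out = set()
            for s in ann.loop_statuses:
                out.add("gained" if s.startswith("gained") else s)
            return out
        if layer == "tad":
            return {ann.tad_status} if ann.tad_status else set()
        if layer == "compartment":
            return {ann.compartment_class} if ann.compartment_class else set()
        raise ValueError(f"unknown layer {layer!r}")

    pool = [a for a in annotated if universe == "all_expressed" or strata_of(a)]
    all_strata = sorted({s for a in pool for s in strata_of(a)})
    results: list[EnrichmentResult] = []
    for direction in ("up", "down"):
        for biotype in ("coding", "noncoding"):
            in_class = [
                a.record.direction == direction and a.record.biotype == biotype for a in pool
            ]
            for stratum in all_strata:
                in_str = [stratum in strata_of(a) for a in pool]
                a_ = sum(1 for ic, is_ in zip(in_class, in_str) if ic and is_)
                b_ = sum(1 for ic, is_ in zip(in_class, in_str) if ic and not is_)
                c_ = sum(1 for ic, is_ in zip(in_class, in_str) if not ic and is_)
                d_ = sum(1 for ic, is_ in zip(in_class, in_str) if not ic and not is_)
                table = ContingencyTable(a_, b_, c_, d_)
                if table.n == 0:
                    continue
                results.append(
                    fisher_enrichment(table, stratum=f"{direction}:{biotype}:{stratum}")
                )
    if results:
        adj = bh_adjust([r.p for r in results])
        results = [
            EnrichmentResult(
                stratum=r.stratum, odds_ratio=r.odds_ratio, ci_low=r.ci_low,
                ci_high=r.ci_high, p=r.p, adj_p=q, table=r.table,
            )
            for r, q in zip(results, adj)
        ]
    return results


# ---------------------------------------------------------------------------
# flow (Sankey) tables
# ---------------------------------------------------------------------------

def sankey_flows(
    annotated: Sequence[AnnotatedTranscript],
    timepoint: str = "",
    include_compartment: bool = True,
) -> list[FlowRecord]:
    """Hierarchical loop -> TAD (-> compartment) flow table.

    For each (direction in {up, down}) x biotype stratum, transcripts with a
    complete path — a gained/lost loop membership (gained takes precedence)
    and a gained/lost TAD status, plus a compartment class when requested —
    are tallied per path; percents within a stratum sum to 100.  Empty
    strata are emitted as zero rows with a warning.
    """
    out: list[FlowRecord] = []
    for direction in ("up", "down"):
        for biotype in ("coding", "noncoding"):
            stratum = f"{direction}:{biotype}"
            members = [
                a for a in annotated
                if a.record.direction == direction and a.record.biotype == biotype
            ]
            paths: dict[str, int] = {}
            for a in members:
                lp = a.flow_loop_status
                if lp not in ("gained", "lost"):
                    continue
                if a.tad_status not in ("gained", "lost"):
                    continue
                path = f"{lp}_loop>{a.tad_status}_tad"
                if include_compartment:
                    if a.compartment_class is None:
                        continue
                    path += f">{a.compartment_class}"
                paths[path] = paths.get(path, 0) + 1
            total = sum(paths.values())
            if total == 0:
                logger.warning("%s: empty flow stratum %s", timepoint, stratum)
                continue
            for path in sorted(paths):
                out.append(
                    FlowRecord(
                        stratum=stratum, path=path, count=paths[path],
                        percent_of_stratum=100.0 * paths[path] / total,
                    )
                )
    return out
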
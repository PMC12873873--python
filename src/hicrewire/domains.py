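"""Differential TAD analysis: reproducibility, sham comparison, fusion/fission.

A TAD is reproducible within a condition when every replicate contains a
domain whose boundaries both lie within ±20 kb of it.  Consensus TADs are
then compared to sham by reciprocal overlap (RO >= 0.8): matched domains are
stable (both boundary displacements <= 10 kb) or shifted; unmatched condition
domains are gained, unmatched sham domains lost.  Fusion/fission events are
detected at a broader ±40 kb tolerance, and merged/split labels are assigned
only to domains already gained or lost, so boundary jitter is never mistaken
for architectural reorganization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .intervals import (
    GenomicInterval,
    boundary_displacement,
    find_overlaps,
)
from .io import DomainCall, RegulatoryElement, ELEMENT_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusDomain",
    "DomainStatus",
    "consensus_domains",
    "compare_to_sham",
    "detect_fusion_fission",
    "stratify_domains",
    "domain_element_density",
    "length_class",
    "strength_class",
]


@dataclass(frozen=True)
class ConsensusDomain:
    """A TAD present in all replicates of one condition.

    Coordinates come from the reference replicate (the first one); the
    boundary score is the mean of the matched replicates' scores.
    """

    interval: GenomicInterval
    boundary_score: float
    condition: str
    support: int


@dataclass(frozen=True)
class DomainStatus:
    """Comparison outcome for one consensus domain (condition or sham side).

    ``status`` partitions condition domains into stable/shifted/gained and
    sham domains additionally into lost.  ``category2`` (merged/split/none)
    marks fusion/fission and is only ever set on gained/lost domains.
    """

    domain: ConsensusDomain
    status: str  # stable | shifted | gained | lost
    category2: str = "none"  # merged | split | none
    partner: GenomicInterval | None = None
    length_class: str | None = None  # lt100kb | 100to400kb | gt400kb
    strength_class: str | None = None  # strong | weak
    derived_from_split: bool = False


def consensus_domains(
    replicate_calls: Sequence[Sequence[DomainCall]],
    tolerance: int = 20_000,
    condition: str = "",
) -> list[ConsensusDomain]:
    """Reproducible TADs: present in every replicate within ±tolerance per end.

    Matching within each non-reference replicate is greedy by nearest total
    boundary displacement, each replicate domain consumed at most once;
    reference domains are processed in genomic order, which makes the result
    deterministic and permutation-stable.
    """
    if not replicate_calls:
        raise ValueError("need >= 1 replicate")
    reference = sorted(replicate_calls[0], key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    others = [list(rep) for rep in replicate_calls[1:]]
    out: list[ConsensusDomain] = []
    used: list[set[int]] = [set() for _ in others]
    for ref in reference:
        scores = [ref.boundary_score]
        matched_all = True
        claims: list[tuple[int, int]] = []
        for r, rep in enumerate(others):
            best: tuple[int, int] | None = None  # (total displacement, index)
            for j, cand in enumerate(rep):
                if j in used[r] or cand.interval.chrom != ref.interval.chrom:
                    continue
                dl, dr = boundary_displacement(ref.interval, cand.interval)
                if dl <= tolerance and dr <= tolerance:
                    key = (dl + dr, j)
                    if best is None or key < best:
                        best = key
            if best is None:
                matched_all = False
                break
            claims.append((r, best[1]))
            scores.append(others[r][best[1]].boundary_score)
        if not matched_all:
            continue
        for r, j in claims:
            used[r].add(j)
        out.append(
            ConsensusDomain(
                interval=ref.interval,
                boundary_score=sum(scores) / len(scores),
                condition=condition or ref.condition,
                support=len(replicate_calls),
            )
        )
    return out


def compare_to_sham(
    sham: Sequence[ConsensusDomain],
    cond: Sequence[ConsensusDomain],
    ro_min: float = 0.8,
    stable_tol: int = 10_000,
) -> list[DomainStatus]:
    """Label condition domains stable/shifted/gained and sham domains lost.

    Candidate pairs must satisfy min(RO) >= ro_min; matching is one-to-one
    greedy by descending min-RO with genomic-position tie-breaks (leftmost
    sham first).  Matched pairs are stable when both boundary displacements
    are <= stable_tol, else shifted.  The returned list carries one record
    per condition domain plus one per unmatched (lost) sham domain.
    """
    sham = sorted(sham, key=lambda d: (d.interval.chrom, d.interval.start, d.interval.end))
    cond = sorted(cond, key=lambda d: (d.interval.chrom, d.interval.start, d.interval.end))
    pairs = find_overlaps([d.interval for d in cond], [d.interval for d in sham])
    candidates = []
    for p in pairs:
        min_ro = min(p.ro_query, p.ro_subject)
        if min_ro >= ro_min:
            s_iv = sham[p.subject_index].interval
            c_iv = cond[p.query_index].interval
            candidates.append((-min_ro, s_iv.chrom, s_iv.start, c_iv.start, p.query_index, p.subject_index))
    candidates.sort()
    matched_cond: dict[int, int] = {}
    matched_sham: set[int] = set()
    for _, _, _, _, qi, si in candidates:
        if qi in matched_cond or si in matched_sham:
            continue
        matched_cond[qi] = si
        matched_sham.add(si)
    out: list[DomainStatus] = []
    for qi, d in enumerate(cond):
        if qi in matched_cond:
            s = sham[matched_cond[qi]]
            dl, dr = boundary_displacement(d.interval, s.interval)
            status = "stable" if (dl <= stable_tol and dr <= stable_tol) else "shifted"
            out.append(DomainStatus(domain=d, status=status, partner=s.interval))
        else:
            out.append(DomainStatus(domain=d, status="gained"))
    for si, s in enumerate(sham):
        if si not in matched_sham:
            out.append(DomainStatus(domain=s, status="lost"))
    return out


def _counts_within(
    target: GenomicInterval,
    others: Sequence[GenomicInterval],
    tolerance: int,
) -> list[int]:
    """Indices of `others` overlapping the ±tolerance-extended target with
    their midpoint inside the extended interval."""
    lo = max(0, target.start - tolerance)
    hi = target.end + tolerance
    hits = []
    for j, o in enumerate(others):
        if o.chrom != target.chrom:
            continue
        if min(hi, o.end) - max(lo, o.start) >= 1 and lo <= o.midpoint < hi:
            hits.append(j)
    return hits


def detect_fusion_fission(
    sham: Sequence[ConsensusDomain],
    cond: Sequence[ConsensusDomain],
    statuses: Sequence[DomainStatus],
    tolerance: int = 40_000,
) -> list[DomainStatus]:
    """Assign merged/split category2 labels to gained/lost domains.

    A gained condition TAD whose ±tolerance extension covers >= 2 sham TADs
    (overlap >= 1 bp and midpoint inside the extension) is merged; a lost
    sham TAD symmetrically covering >= 2 condition TADs is split, and the
    covered condition domains — the fission products — are flagged
    ``derived_from_split``.  Status labels are never altered here.
    """
    sham_ivs = [d.interval for d in sham]
    cond_ivs = [d.interval for d in cond]
    cond_index = {d.interval: i for i, d in enumerate(cond)}
    split_children: set[int] = set()
    updated: list[DomainStatus] = []
    for st in statuses:
        if st.status == "gained":
            hits = _counts_within(st.domain.interval, sham_ivs, tolerance)
            cat = "merged" if len(hits) >= 2 else "none"
            updated.append(replace(st, category2=cat))
        elif st.status == "lost":
            hits = _counts_within(st.domain.interval, cond_ivs, tolerance)
            cat = "split" if len(hits) >= 2 else "none"
            if cat == "split":
                split_children.update(hits)
            updated.append(replace(st, category2=cat))
        else:
            updated.append(replace(st, category2="none"))
    # second pass: flag gained fission products of split sham parents
    final: list[DomainStatus] = []
    for st in updated:
        idx = cond_index.get(st.domain.interval)
        if st.status == "gained" and idx is not None and idx in split_children:
            final.append(replace(st, derived_from_split=True))
        else:
            final.append(st)
    return final


def length_class(length_bp: int) -> str:
    """Length stratum: < 100 kb, [100 kb, 400 kb), or >= 400 kb."""
    if length_bp < 100_000:
        return "lt100kb"
    if length_bp < 400_000:
        return "100to400kb"
    return "gt400kb"


def strength_class(boundary_score: float, strong_z: float = 1.0) -> str:
    """Strong boundary iff z-score strictly above the threshold (default 1)."""
    return "strong" if boundary_score > strong_z else "weak"


def stratify_domains(
    statuses: Sequence[DomainStatus], strong_z: float = 1.0
) -> list[DomainStatus]:
    """Attach length and boundary-strength strata to every status record."""
    return [
        replace(
            st,
            length_class=length_class(len(st.domain.interval)),
            strength_class=strength_class(st.domain.boundary_score, strong_z),
        )
        for st in statuses
    ]


def domain_element_density(
    domains: Sequence[ConsensusDomain] | Sequence[DomainStatus],
    elements: Sequence[RegulatoryElement],
) -> list[dict]:
    """Per-domain regulatory-element counts and densities per element class.

    Any overlap (>= 1 bp) counts an element; density is count per kb of
    domain length.  Returns one dict per domain with ``count_<class>`` and
    ``density_<class>`` entries.
    """
    ivs = [
        (d.domain.interval if isinstance(d, DomainStatus) else d.interval) for d in domains
    ]
    pairs = find_overlaps(ivs, [e.interval for e in elements])
    counts = [{cls: 0 for cls in ELEMENT_CLASSES} for _ in ivs]
    for p in pairs:
        counts[p.query_index][elements[p.subject_index].element_class] += 1
    out = []
    for iv, cnt in zip(ivs, counts):
        row: dict = {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
        for cls in ELEMENT_CLASSES:
            row[f"count_{cls}"] = cnt[cls]
            row[f"density_{cls}"] = cnt[cls] / (len(iv) / 1000.0)
        out.append(row)
    return out
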
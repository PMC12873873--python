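"""Chromatin-loop reproducibility, strength/length classes, and differential calls.

Within a condition a loop (identified by its exact anchor coordinates) is
reproducible when it is present — and passes significance — in every
biological replicate; a replicate call passes when some context (BL, Donut,
H or V) has adjusted p < 0.05 with an observed bin count >= 3.  Reproducible
loops are classified strong / weak / intermediate from their per-context
statistics and short / long by anchor span.  Differential status across
sham, 6 h and 24 h reperfusion uses exact-anchor presence over the union of
reproducible loops; no fuzzy anchor matching is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import GenomicInterval
from .io import ContextStats, LoopCall, RegulatoryElement, ELEMENT_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ReproducibleLoop",
    "LoopDelta",
    "LoopKey",
    "passes_significance",
    "reproducible_loops",
    "classify_strength",
    "classify_length",
    "diff_loops",
    "loop_tad_context",
    "context_three_way",
    "anchor_element_density",
]

LoopKey = tuple[str, int, int, int, int]


@dataclass(frozen=True)
class ReproducibleLoop:
    """A loop present and passing in all replicates of one condition.

    Per-context statistics are carried from the reference replicate (the
    first); strength/length classes are derived from them.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    stats: Mapping[str, ContextStats]
    condition: str
    strength: str  # strong | weak | intermediate
    length_class: str  # short | long

    @property
    def key(self) -> LoopKey:
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
class LoopDelta:
    """Differential status of one loop key over sham / 6 h / 24 h presence.

    ``status`` is the strict reading (lost = present in sham, absent at both
    reperfusion timepoints); ``lost_6h`` / ``lost_24h`` expose the
    per-timepoint reading as well.  A loop absent in sham but present at both
    timepoints is labeled by first appearance (gained_6h).
    """

    key: LoopKey
    in_sham: bool
    in_6h: bool
    in_24h: bool
    status: str  # gained_6h | gained_24h | lost | stable
    lost_6h: bool
    lost_24h: bool


def passes_significance(
    stats: Mapping[str, ContextStats],
    adj_p_max: float = 0.05,
    min_count: int = 3,
) -> bool:
    """True iff some context has adj_p < threshold and observed >= min count."""
    return any(
        s.adj_p < adj_p_max and s.observed >= min_count for s in stats.values()
    )


def classify_strength(
    stats: Mapping[str, ContextStats],
    strong_obs: float = 15,
    strong_oe: float = 2.5,
    strong_adj_p: float = 0.05,
    weak_obs: float = 10,
    weak_oe: float = 1.5,
) -> str:
    """Strong / weak / intermediate from per-context statistics.

    Strong: some context with observed >= 15, obs/exp >= 2.5 and adj p < 0.05.
    Weak: every context has observed < 10 and obs/exp < 1.5.
    Anything else is intermediate.
    """
    if any(
        s.observed >= strong_obs and s.oe >= strong_oe and s.adj_p < strong_adj_p
        for s in stats.values()
    ):
        return "strong"
    if all(s.observed < weak_obs and s.oe < weak_oe for s in stats.values()):
        return "weak"
    return "intermediate"


def classify_length(span: int, cut: int = 200_000) -> str:
    """Short (< 200 kb) vs long (>= 200 kb) by anchor-start span."""
    return "short" if span < cut else "long"


def reproducible_loops(
    replicate_calls: Sequence[Sequence[LoopCall]],
    condition: str = "",
    adj_p_max: float = 0.05,
    min_count: int = 3,
    strong_obs: float = 15,
    strong_oe: float = 2.5,
    strong_adj_p: float = 0.05,
    weak_obs: float = 10,
    weak_oe: float = 1.5,
    length_cut: int = 200_000,
) -> list[ReproducibleLoop]:
    """Loops present and passing in every replicate, keyed by exact anchors."""
    if not replicate_calls:
        raise ValueError("need >= 1 replicate")
    by_key: list[dict[LoopKey, LoopCall]] = []
    for rep in replicate_calls:
        d: dict[LoopKey, LoopCall] = {}
        for call in rep:
            if call.key in d:
                logger.warning("duplicate loop key %s within a replicate; keeping first", call.key)
                continue
            d[call.key] = call
        by_key.append(d)
    reference = by_key[0]
    out: list[ReproducibleLoop] = []
    for key in sorted(reference):
        calls = [d.get(key) for d in by_key]
        if any(c is None for c in calls):
            continue
        if not all(passes_significance(c.stats, adj_p_max, min_count) for c in calls):
            continue
        ref = reference[key]
        out.append(
            ReproducibleLoop(
                anchor1=ref.anchor1,
                anchor2=ref.anchor2,
                stats=ref.stats,
                condition=condition or ref.condition,
                strength=classify_strength(
                    ref.stats, strong_obs, strong_oe, strong_adj_p, weak_obs, weak_oe
                ),
                length_class=classify_length(ref.span, length_cut),
            )
        )
    return out


def diff_loops(
    sham_set: Sequence[ReproducibleLoop],
    set_6h: Sequence[ReproducibleLoop],
    set_24h: Sequence[ReproducibleLoop],
) -> list[LoopDelta]:
    """Gained/lost/stable status over the union of reproducible loop keys.

    Strict mode (the default reported ``status``): gained_6h = present at 6 h
    and absent in sham; gained_24h = present at 24 h, absent in sham and at
    6 h; lost = present in sham, absent at both timepoints; stable = present
    in sham and at >= 1 timepoint.  The per-timepoint reading (lost at a
    given timepoint = in sham but absent there) is carried as flags.
    """
    keys_sham = {l.key for l in sham_set}
    keys_6h = {l.key for l in set_6h}
    keys_24h = {l.key for l in set_24h}
    out: list[LoopDelta] = []
    for key in sorted(keys_sham | keys_6h | keys_24h):
        s, h6, h24 = key in keys_sham, key in keys_6h, key in keys_24h
        if s:
            status = "lost" if not (h6 or h24) else "stable"
        else:
            status = "gained_6h" if h6 else "gained_24h"
        out.append(
            LoopDelta(
                key=key, in_sham=s, in_6h=h6, in_24h=h24, status=status,
                lost_6h=s and not h6, lost_24h=s and not h24,
            )
        )
    return out


def loop_tad_context(
    loop: ReproducibleLoop | LoopCall, tads: Sequence
) -> str:
    """Four-way loop-vs-TAD context from anchor midpoints.

    inside: both anchor midpoints in the same TAD; outside: neither in any
    TAD; one_anchor: exactly one inside; inter_tad: midpoints in two
    different TADs (a domain-bridging loop).  TADs must come from the loop's
    own condition.
    """
    def _containing(pos: int, chrom: str):
        for i, t in enumerate(tads):
            iv = t.interval if hasattr(t, "interval") else t
            if iv.chrom == chrom and iv.contains_point(pos):
                return i
        return None

    t1 = _containing(loop.anchor1.midpoint, loop.anchor1.chrom)
    t2 = _containing(loop.anchor2.midpoint, loop.anchor2.chrom)
    if t1 is None and t2 is None:
        return "outside"
    if t1 is not None and t2 is not None:
        return "inside" if t1 == t2 else "inter_tad"
    return "one_anchor"


def context_three_way(context: str) -> str:
    """Map the four-way context onto inside / outside / cross_boundary."""
    return {"inside": "inside", "outside": "outside"}.get(context, "cross_boundary")


def anchor_element_density(
    loops: Sequence[ReproducibleLoop],
    elements: Sequence[RegulatoryElement],
) -> list[dict]:
    """Per-loop, per-anchor regulatory element counts and densities.

    An element overlapping both anchors of a short loop is counted at both;
    density is count per kb of anchor width.
    """
    from .intervals import find_overlaps

    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.extend((lp.anchor1, lp.anchor2))
    pairs = find_overlaps(anchors, [e.interval for e in elements])
    counts = [{cls: 0 for cls in ELEMENT_CLASSES} for _ in anchors]
    for p in pairs:
        counts[p.query_index][elements[p.subject_index].element_class] += 1
    out = []
    for i, lp in enumerate(loops):
        row: dict = {
            "chrom": lp.anchor1.chrom,
            "start1": lp.anchor1.start, "end1": lp.anchor1.end,
            "start2": lp.anchor2.start, "end2": lp.anchor2.end,
        }
        for a_idx, a_name in ((2 * i, "anchor1"), (2 * i + 1, "anchor2")):
            width_kb = len(anchors[a_idx]) / 1000.0
            for cls in ELEMENT_CLASSES:
                c = counts[a_idx][cls]
                row[f"count_{cls}_{a_name}"] = c
                row[f"density_{cls}_{a_name}"] = c / width_kb
        out.append(row)
    return out
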
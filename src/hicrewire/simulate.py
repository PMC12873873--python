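"""Seeded synthetic Hi-C feature scene with a planted ground-truth manifest.

The study whose design this generator emulates compared sham-operated mouse
cortex against 6 h and 24 h reperfusion after transient occlusion, with three
biological replicates per condition, compartment eigenvectors at 1 Mb, and
TADs/loops called at 10 kb.  No raw data are deposited, so this module
constructs every pipeline input from scratch:

* per-replicate eigenvector bedGraphs with planted A/B labels and switch
  classes (the class fractions default to those observed in the study);
* per-replicate Arrowhead-style domain lists with planted stable / shifted /
  gained / lost / merged / split events and replicate boundary jitter;
* per-replicate HiCCUPS-style loop lists whose per-context statistics are
  drawn constructively to guarantee the intended pass / strength labels;
* regulatory-element BEDs with a density contrast between gained and lost
  domains, a gene-density track, a centromere/telomere blacklist;
* a transcript differential-expression table whose transcripts are routed
  onto loop anchors along configurable loop->TAD path weights and with a
  planted enrichment odds ratio.

Everything derives from one ``numpy`` generator seeded by the caller, and the
manifest (``truth.json``) records every planted event, so the pipeline's
recovery can be checked exactly.  Regenerating with the same seed reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import (
    CONDITIONS,
    CONTEXTS,
    ContextStats,
    DomainCall,
    EigenvectorTrack,
    LoopCall,
    RegulatoryElement,
    TranscriptRecord,
    write_bed_elements,
    write_blacklist,
    write_domain_list,
    write_eigenvector_bedgraph,
    write_loop_list,
    write_transcripts,
)

__all__ = ["SimulationConfig", "TruthManifest", "generate_dataset", "corrupt_dataset",
           "enrichment_draws"]

TIMEPOINTS = ("rep_6h", "rep_24h")
RES = 10_000  # loop-anchor / TAD calling resolution


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Scene parameters; the defaults are the study design the scene emulates."""

    chromosomes: dict = field(default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    bin_size: int = 1_000_000
    replicates: int = 3
    blacklist_bins_per_chrom: int = 1  # leading bin(s) stand in for centromeres

    # compartment switch fractions per timepoint (study-reported proportions)
    switch_fractions: dict = field(default_factory=lambda: {
        "rep_6h": {"AtoB": 0.29, "BtoA": 0.29, "StableA": 0.21, "StableB": 0.21},
        "rep_24h": {"AtoB": 0.25, "BtoA": 0.26, "StableA": 0.26, "StableB": 0.23},
    })
    stable_mag: tuple = (0.9, 1.6)     # |eigenvalue| of never-switching bins
    switch_mag: tuple = (0.10, 0.30)   # |eigenvalue| of ever-switching bins
    replicate_noise_sd: float = 0.05   # multiplicative log-normal noise per replicate

    # TAD slot composition per chromosome and per-timepoint event quotas
    n_pair_slots: int = 3
    n_single_slots: int = 18
    n_empty_slots: int = 9
    n_decoy_slots: int = 2
    pair_events: dict = field(default_factory=lambda: {"merged": 2, "stable_pair": 1})
    single_events: dict = field(default_factory=lambda: {"stable": 10, "shifted": 3, "lost": 3, "split": 2})
    empty_events: dict = field(default_factory=lambda: {"gained": 6, "none": 3})
    jitter_sd: float = 2_000.0
    jitter_max: float = 5_000.0
    decoy_offset: int = 25_000  # beyond the ±20 kb reproducibility tolerance
    score_noise_sd: float = 0.03

    # loop universe: presence patterns over (sham, 6 h, 24 h)
    loop_pattern_counts: dict = field(default_factory=lambda: {
        "111": 180, "110": 25, "101": 20, "100": 50, "010": 70, "001": 40, "011": 25,
    })
    loop_strength_weights: tuple = (0.4, 0.3, 0.3)  # strong / weak / intermediate
    loop_short_frac: float = 0.55
    n_routing_per_path: int = 6
    n_partial_decoys: int = 10   # present in replicates 1..(n-1) only
    n_failing_decoys: int = 10   # present everywhere, observed = 2 in one replicate

    # transcripts
    n_routed_per_tp: int = 400
    routing_weights: dict = field(default_factory=lambda: {
        "gained_loop>gained_tad": 46.0,
        "lost_loop>gained_tad": 33.0,
        "gained_loop>lost_tad": 14.0,
        "lost_loop>lost_tad": 11.0,
    })
    n_enrichment: int = 2_000
    planted_or: float = 2.0
    enrich_class_p: float = 0.3   # P(transcript is noncoding & upregulated)
    enrich_base_p: float = 0.25   # P(in lost loop | not in class)
    n_background: int = 300

    # regulatory elements: (per-100kb density in gained TADs, in lost TADs,
    # flat background count per chromosome)
    element_densities: dict = field(default_factory=lambda: {
        "enhancer": (2.5, 0.8, 20),
        "promoter": (1.2, 0.6, 10),
        "ctcf": (1.0, 0.8, 15),
        "super_enhancer": (0.3, 0.1, 3),
        "stroke_super_enhancer": (0.25, 0.0, 1),
    })

    def validate(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0 or length % self.bin_size:
                raise ValueError(f"{chrom}: length must be a positive multiple of bin_size")
        for tp, fr in self.switch_fractions.items():
            s = sum(fr.values())
            if not math.isclose(s, 1.0, abs_tol=1e-9) or min(fr.values()) < 0:
                raise ValueError(f"{tp}: switch fractions must be non-negative and sum to 1 (got {s})")
        if sum(self.pair_events.values()) != self.n_pair_slots:
            raise ValueError("pair_events must sum to n_pair_slots")
        if sum(self.single_events.values()) != self.n_single_slots:
            raise ValueError("single_events must sum to n_single_slots")
        if sum(self.empty_events.values()) != self.n_empty_slots:
            raise ValueError("empty_events must sum to n_empty_slots")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.jitter_max > 20_000:
            raise ValueError("jitter_max beyond the reproducibility tolerance would break planted truth")
        need_100 = 2 * len(TIMEPOINTS) * self.n_routing_per_path
        if self.loop_pattern_counts.get("100", 0) < need_100:
            raise ValueError("not enough lost loops ('100') for transcript routing")
        if self.loop_pattern_counts.get("010", 0) < 2 * self.n_routing_per_path:
            raise ValueError("not enough 6h-gained loops ('010') for transcript routing")
        if self.loop_pattern_counts.get("001", 0) < 2 * self.n_routing_per_path:
            raise ValueError("not enough 24h-gained loops ('001') for transcript routing")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")


@dataclass
class TruthManifest:
    """Machine-readable record of every planted event (saved as truth.json)."""

    data: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(data=json.load(fh))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _apportion(total: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder integer apportionment of `total` over `fracs`."""
    raw = [total * f for f in fracs]
    base = [int(math.floor(x)) for x in raw]
    rem = total - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def _grid(x: float) -> int:
    return int(round(x / RES)) * RES


class _BinPool:
    """Allocator of unique, non-overlapping 10 kb anchor bins."""

    def __init__(self, chromosomes: dict, rng: np.random.Generator):
        self.chromosomes = chromosomes
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def take(self, chrom: str, start: int) -> bool:
        key = (chrom, start)
        if key in self.used:
            return False
        self.used.add(key)
        return True

    def random_bin(self, chrom: str | None = None, lo: int = 1_000_000,
                   margin: int = 0) -> tuple[str, int]:
        for _ in range(10_000):
            c = chrom or sorted(self.chromosomes)[int(self.rng.integers(len(self.chromosomes)))]
            top = self.chromosomes[c] - margin - RES
            if top < lo:
                continue
            start = _grid(float(self.rng.integers(lo // RES, top // RES + 1)) * RES)
            if self.take(c, start):
                return c, start
        raise RuntimeError("anchor-bin pool exhausted")

    def bin_inside(self, iv: GenomicInterval) -> tuple[str, int]:
        candidates = list(range(math.ceil(iv.start / RES), (iv.end - RES) // RES + 1))
        self.rng.shuffle(candidates)
        for b in candidates:
            if self.take(iv.chrom, b * RES):
                return iv.chrom, b * RES
        raise RuntimeError(f"no free anchor bin inside {iv}")


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def _plant_compartments(cfg: SimulationConfig, rng: np.random.Generator,
                        blacklist: list[GenomicInterval]):
    """Assign sham labels and per-timepoint switch classes per retained bin.

    Switching at 24 h is nested within the 6 h switch set (or vice versa when
    the 24 h quota is larger), emulating partial normalization and guaranteeing
    each chromosome keeps a block of strong never-switching bins — that is what
    keeps the gene-density orientation of every sample sign-determinate.
    """
    bins: list[GenomicInterval] = []
    for chrom in sorted(cfg.chromosomes):
        for s in range(0, cfg.chromosomes[chrom], cfg.bin_size):
            bins.append(GenomicInterval(chrom, s, s + cfg.bin_size))
    black = {(iv.chrom, iv.start) for iv in blacklist}
    retained = [iv for iv in bins if (iv.chrom, iv.start) not in black]

    plan: dict[GenomicInterval, dict] = {}
    f6 = cfg.switch_fractions["rep_6h"]
    f24 = cfg.switch_fractions["rep_24h"]
    for chrom in sorted(cfg.chromosomes):
        chrom_bins = [iv for iv in retained if iv.chrom == chrom]
        n = len(chrom_bins)
        n_atob6, n_btoa6, n_stA6, n_stB6 = _apportion(
            n, [f6["AtoB"], f6["BtoA"], f6["StableA"], f6["StableB"]]
        )
        n_a = n_atob6 + n_stA6
        n_b = n - n_a
        fa = f24["AtoB"] / (f24["AtoB"] + f24["StableA"])
        fb = f24["BtoA"] / (f24["BtoA"] + f24["StableB"])
        n_atob24 = _apportion(n_a, [fa, 1 - fa])[0]
        n_btoa24 = _apportion(n_b, [fb, 1 - fb])[0]
        perm = [chrom_bins[i] for i in rng.permutation(n)]
        a_bins, b_bins = perm[:n_a], perm[n_a:]
        for iv in chrom_bins:
            plan[iv] = {}
        # nested switch sets: the smaller switch quota is a subset of the larger
        for sham_label, group, k6, k24, sw_class in (
            ("A", a_bins, n_atob6, n_atob24, "AtoB"),
            ("B", b_bins, n_btoa6, n_btoa24, "BtoA"),
        ):
            shuffled = [group[i] for i in rng.permutation(len(group))]
            k_max = max(k6, k24)
            for i, iv in enumerate(shuffled):
                sw6 = i < k6
                sw24 = i < k24
                plan[iv] = {
                    "sham": sham_label,
                    "class_6h": sw_class if sw6 else f"Stable{sham_label}",
                    "class_24h": sw_class if sw24 else f"Stable{sham_label}",
                    "ever_switch": i < k_max,
                }
    return bins, retained, plan


def _write_eigen_tracks(cfg, rng, out_dir: Path, bins, retained, plan, blacklist):
    """Write per-condition, per-replicate eigenvector tracks and gene density."""
    other = {"A": "B", "B": "A"}
    base_mag = {}
    for iv in retained:
        lo, hi = cfg.switch_mag if plan[iv]["ever_switch"] else cfg.stable_mag
        base_mag[iv] = float(rng.uniform(lo, hi))
    # gene density tied to the sham-signed base magnitude (A-rich bins are gene dense)
    density = {}
    for iv in bins:
        if iv in base_mag:
            signed = base_mag[iv] if plan[iv]["sham"] == "A" else -base_mag[iv]
        else:
            signed = 0.0
        density[iv] = max(0.1, 5.0 + 3.0 * signed + float(rng.normal(0, 0.3)))
    dens_track = EigenvectorTrack(
        bins=[(iv, density[iv]) for iv in bins], bin_size=cfg.bin_size,
        sample_id="gene_density", condition="", replicate=0,
    )
    (out_dir / "eigen").mkdir(parents=True, exist_ok=True)
    write_eigenvector_bedgraph(dens_track, out_dir / "gene_density.bedgraph")

    label_key = {"sham": "sham", "rep_6h": "class_6h", "rep_24h": "class_24h"}
    for cond in CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            # per-chromosome random sign flip: PC1 sign is arbitrary
            flips = {c: (-1.0 if rng.random() < 0.5 else 1.0) for c in sorted(cfg.chromosomes)}
            values: dict[GenomicInterval, float] = {}
            for chrom in sorted(cfg.chromosomes):
                chrom_bins = [iv for iv in retained if iv.chrom == chrom]
                raw = []
                for iv in chrom_bins:
                    info = plan[iv]
                    if cond == "sham":
                        label = info["sham"]
                    else:
                        cls = info[label_key[cond]]
                        label = other[info["sham"]] if cls in ("AtoB", "BtoA") else info["sham"]
                    mag = base_mag[iv] * float(np.exp(rng.normal(0, cfg.replicate_noise_sd)))
                    raw.append(mag if label == "A" else -mag)
                raw = np.array(raw)
                # rebalance A vs B mass so the chromosome mean is exactly zero:
                # genome-wide z-scoring then cannot move any bin across zero
                s_pos = raw[raw > 0].sum()
                s_neg = -raw[raw < 0].sum()
                target = (s_pos + s_neg) / 2
                raw = np.where(raw > 0, raw * target / s_pos, raw * target / s_neg)
                for iv, v in zip(chrom_bins, raw):
                    values[iv] = flips[chrom] * float(v)
            track_bins = []
            for iv in bins:
                v = values.get(iv, float(rng.normal(0, 0.5)))  # blacklisted bins: junk
                track_bins.append((iv, v))
            track = EigenvectorTrack(
                bins=track_bins, bin_size=cfg.bin_size,
                sample_id=f"{cond}_rep{rep}", condition=cond, replicate=rep,
            )
            write_eigenvector_bedgraph(track, out_dir / "eigen" / f"{cond}_rep{rep}.bedgraph")


# ---------------------------------------------------------------------------
# TADs
# ---------------------------------------------------------------------------

def _layout_tad_slots(cfg, rng) -> list[dict]:
    """Place slot geometry (sham content fixed; per-timepoint events live in slots)."""
    slots: list[dict] = []
    for chrom in sorted(cfg.chromosomes):
        kinds = (
            ["pair"] * cfg.n_pair_slots + ["single"] * cfg.n_single_slots
            + ["empty"] * cfg.n_empty_slots + ["decoy"] * cfg.n_decoy_slots
        )
        kinds = [kinds[i] for i in rng.permutation(len(kinds))]
        cursor = 1_100_000
        for kind in kinds:
            gap = _grid(rng.uniform(60_000, 90_000))
            if kind == "pair":
                l1 = _grid(rng.uniform(150_000, 180_000))
                l2 = _grid(rng.uniform(150_000, 180_000))
                s1 = GenomicInterval(chrom, cursor, cursor + l1)
                s2 = GenomicInterval(chrom, cursor + l1 + 30_000, cursor + l1 + 30_000 + l2)
                slots.append({"kind": "pair", "chrom": chrom, "sham": [s1, s2]})
                cursor = s2.end + gap
            elif kind == "single":
                length = _grid(rng.uniform(410_000, 500_000))
                s = GenomicInterval(chrom, cursor, cursor + length)
                slots.append({"kind": "single", "chrom": chrom, "sham": [s]})
                cursor = s.end + gap
            elif kind == "empty":
                slots.append({"kind": "empty", "chrom": chrom, "start": cursor, "width": 400_000})
                cursor += 400_000 + gap
            else:  # decoy
                slots.append({"kind": "decoy", "chrom": chrom, "start": cursor, "width": 250_000})
                cursor += 250_000 + gap
        if cursor > cfg.chromosomes[chrom]:
            raise ValueError(f"{chrom}: TAD slot layout exceeds chromosome length (infeasible config)")
    return slots


def _draw_score(rng, status: str) -> float:
    """Boundary z-score away from the strong/weak threshold of 1 by >= 0.15,
    so averaging over jittered replicate scores never flips the class."""
    if status == "gained":
        return float(rng.uniform(0.3, 0.85))
    if rng.random() < 0.6:
        return float(rng.uniform(1.15, 2.2))
    return float(rng.uniform(0.3, 0.85))


def _plant_tads(cfg, rng, slots):
    """Assign per-timepoint events to slots; return planted domain records.

    Returns (sham_domains, per-tp condition domains with expected status and
    category2, per-tp expected lost-sham records, decoys).
    """
    sham_domains: list[dict] = []
    for slot in slots:
        for iv in slot.get("sham", []):
            sham_domains.append({
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "score": _draw_score(rng, "sham"),
            })
    planted = {tp: {"cond": [], "lost": []} for tp in TIMEPOINTS}
    for tp in TIMEPOINTS:
        for chrom in sorted(cfg.chromosomes):
            chrom_slots = [s for s in slots if (s.get("chrom") == chrom)]
            pair_slots = [s for s in chrom_slots if s["kind"] == "pair"]
            single_slots = [s for s in chrom_slots if s["kind"] == "single"]
            empty_slots = [s for s in chrom_slots if s["kind"] == "empty"]
            pair_ev = sum(([k] * v for k, v in sorted(cfg.pair_events.items())), [])
            single_ev = sum(([k] * v for k, v in sorted(cfg.single_events.items())), [])
            empty_ev = sum(([k] * v for k, v in sorted(cfg.empty_events.items())), [])
            pair_ev = [pair_ev[i] for i in rng.permutation(len(pair_ev))]
            single_ev = [single_ev[i] for i in rng.permutation(len(single_ev))]
            empty_ev = [empty_ev[i] for i in rng.permutation(len(empty_ev))]

            def add_cond(iv, status, cat="none", derived=False):
                planted[tp]["cond"].append({
                    "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "status": status, "category2": cat, "derived_from_split": derived,
                    "score": _draw_score(rng, status),
                })

            def add_lost(iv, cat="none"):
                planted[tp]["lost"].append({
                    "chrom": iv.chrom, "start": iv.start, "end": iv.end, "category2": cat,
                })

            for slot, ev in zip(pair_slots, pair_ev):
                s1, s2 = slot["sham"]
                if ev == "merged":
                    fused = GenomicInterval(s1.chrom, s1.start, s2.end)
                    add_cond(fused, "gained", cat="merged")
                    add_lost(s1)
                    add_lost(s2)
                else:  # stable_pair
                    add_cond(s1, "stable")
                    add_cond(s2, "stable")
            for slot, ev in zip(single_slots, single_ev):
                (s,) = slot["sham"]
                if ev == "stable":
                    add_cond(s, "stable")
                elif ev == "shifted":
                    delta = int(rng.choice([30_000, 40_000, 50_000]))
                    if rng.random() < 0.5:
                        shifted = GenomicInterval(s.chrom, s.start + delta, s.end)
                    else:
                        shifted = GenomicInterval(s.chrom, s.start, s.end - delta)
                    add_cond(shifted, "shifted")
                elif ev == "lost":
                    add_lost(s)
                else:  # split
                    lc = _grid((len(s) - 40_000) / 2)
                    c1 = GenomicInterval(s.chrom, s.start, s.start + lc)
                    c2 = GenomicInterval(s.chrom, s.start + lc + 40_000, s.end)
                    add_cond(c1, "gained", derived=True)
                    add_cond(c2, "gained", derived=True)
                    add_lost(s, cat="split")
            for slot, ev in zip(empty_slots, empty_ev):
                if ev == "gained":
                    length = _grid(rng.uniform(100_000, 390_000))
                    iv = GenomicInterval(slot["chrom"], slot["start"], slot["start"] + length)
                    add_cond(iv, "gained")
    decoys = [
        {"chrom": s["chrom"], "start": s["start"], "end": s["start"] + 200_000}
        for s in slots if s["kind"] == "decoy"
    ]
    return sham_domains, planted, decoys


def _write_domain_files(cfg, rng, out_dir: Path, sham_domains, planted, decoys):
    (out_dir / "domains").mkdir(parents=True, exist_ok=True)

    def jitter() -> int:
        j = rng.normal(0, cfg.jitter_sd)
        return int(round(max(-cfg.jitter_max, min(cfg.jitter_max, j))))

    for cond in CONDITIONS:
        if cond == "sham":
            records = [dict(d) for d in sham_domains]
        else:
            records = [
                {"chrom": d["chrom"], "start": d["start"], "end": d["end"], "score": d["score"]}
                for d in planted[cond]["cond"]
            ]
        for rep in range(1, cfg.replicates + 1):
            calls = []
            for d in records:
                start, end = d["start"], d["end"]
                if rep > 1:
                    start, end = start + jitter(), end + jitter()
                calls.append(DomainCall(
                    interval=GenomicInterval(d["chrom"], start, end),
                    boundary_score=d["score"] + float(rng.normal(0, cfg.score_noise_sd)),
                    sample_id=f"{cond}_rep{rep}", condition=cond, replicate=rep,
                ))
            for dec in decoys:
                start, end = dec["start"], dec["end"]
                if rep == 2:  # one replicate displaced beyond tolerance: not reproducible
                    start += cfg.decoy_offset
                    end += cfg.decoy_offset
                calls.append(DomainCall(
                    interval=GenomicInterval(dec["chrom"], start, end),
                    boundary_score=float(rng.uniform(0.3, 2.0)),
                    sample_id=f"{cond}_rep{rep}", condition=cond, replicate=rep,
                ))
            calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
            write_domain_list(calls, out_dir / "domains" / f"{cond}_rep{rep}.tsv")


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def _draw_span(cfg, rng) -> int:
    if rng.random() < cfg.loop_short_frac:
        return _grid(rng.uniform(30_000, 190_000))
    return _grid(rng.uniform(200_000, 900_000))


def _make_stats(rng, intent: str, failing: bool = False) -> dict[str, ContextStats]:
    """Per-context statistics drawn constructively to guarantee a label.

    intent: strong / weak / intermediate (all of which pass significance);
    failing=True instead guarantees the pass rule fails (observed = 2 with
    large adjusted p everywhere).
    """
    stats = {}
    if failing:
        for ctx in CONTEXTS:
            stats[ctx] = ContextStats(observed=2, oe=float(rng.uniform(0.8, 1.4)),
                                      adj_p=float(rng.uniform(0.2, 0.9)))
        return stats
    star = CONTEXTS[int(rng.integers(len(CONTEXTS)))]
    for ctx in CONTEXTS:
        if ctx == star:
            if intent == "strong":
                stats[ctx] = ContextStats(observed=int(rng.integers(15, 41)),
                                          oe=float(rng.uniform(2.5, 6.0)),
                                          adj_p=float(rng.uniform(1e-8, 0.04)))
            elif intent == "weak":
                stats[ctx] = ContextStats(observed=int(rng.integers(3, 10)),
                                          oe=float(rng.uniform(0.5, 1.4)),
                                          adj_p=float(rng.uniform(1e-4, 0.04)))
            else:  # intermediate: passes, too strong for weak, too weak for strong
                stats[ctx] = ContextStats(observed=int(rng.integers(10, 15)),
                                          oe=float(rng.uniform(1.6, 2.4)),
                                          adj_p=float(rng.uniform(1e-4, 0.04)))
        else:
            stats[ctx] = ContextStats(observed=int(rng.integers(3, 9)),
                                      oe=float(rng.uniform(0.5, 1.4)),
                                      adj_p=float(rng.uniform(0.1, 0.95)))
    return stats


def _plant_loops(cfg, rng, pool: _BinPool, planted_tads):
    """Build the loop-key universe with presence patterns and routing pools.

    Routing loops guarantee, per timepoint, loops of each flow path: a
    gained/lost loop whose first anchor sits inside a gained/lost TAD of that
    timepoint.  The remaining quota of each presence pattern is placed on
    random unused anchor bins.
    """
    loops: list[dict] = []
    routing_pools: dict[tuple[str, str], list[int]] = {}
    quotas = dict(cfg.loop_pattern_counts)
    pattern_for_gain = {"rep_6h": "010", "rep_24h": "001"}

    def host_domains(tp: str, tad_part: str):
        if tad_part == "gained_tad":
            return [d for d in planted_tads[tp]["cond"] if d["status"] == "gained"]
        return [d for d in planted_tads[tp]["lost"] if d["category2"] == "none"
                and not _covered_by_cond(d, planted_tads[tp]["cond"])]

    def _covered_by_cond(lost, conds):
        mid = (lost["start"] + lost["end"]) // 2
        return any(c["chrom"] == lost["chrom"] and c["start"] <= mid < c["end"] for c in conds)

    def new_loop(pattern: str, chrom: str, a1: int, intent: str | None = None) -> int:
        a2 = None
        for _ in range(200):
            span = _draw_span(cfg, rng)
            if a1 + span + RES <= cfg.chromosomes[chrom] and pool.take(chrom, a1 + span):
                a2 = a1 + span
                break
        if a2 is None:  # deterministic fallback near the chromosome end
            for span in range(30_000, 200_000, RES):
                if a1 + span + RES <= cfg.chromosomes[chrom] and pool.take(chrom, a1 + span):
                    a2 = a1 + span
                    break
        if a2 is None:
            raise RuntimeError("could not place second anchor")
        intent = intent or str(rng.choice(["strong", "weak", "intermediate"],
                                          p=cfg.loop_strength_weights))
        loops.append({
            "key": [chrom, a1, a1 + RES, a2, a2 + RES],
            "pattern": pattern, "intent": intent,
        })
        return len(loops) - 1

    for tp in TIMEPOINTS:
        for loop_part, pattern in (("gained_loop", pattern_for_gain[tp]), ("lost_loop", "100")):
            for tad_part in ("gained_tad", "lost_tad"):
                hosts = host_domains(tp, tad_part)
                pool_ids = []
                for _ in range(cfg.n_routing_per_path):
                    host = hosts[int(rng.integers(len(hosts)))]
                    chrom, a1 = pool.bin_inside(
                        GenomicInterval(host["chrom"], host["start"], host["end"])
                    )
                    idx = new_loop(pattern, chrom, a1)
                    quotas[pattern] -= 1
                    pool_ids.append(idx)
                routing_pools[(tp, f"{loop_part}>{tad_part}")] = pool_ids
    for pattern in sorted(quotas):
        for _ in range(quotas[pattern]):
            # leave end margin so at least every short span fits downstream
            chrom, a1 = pool.random_bin(margin=200_000)
            new_loop(pattern, chrom, a1)

    decoys = []
    for kind, n in (("partial", cfg.n_partial_decoys), ("failing", cfg.n_failing_decoys)):
        for _ in range(n):
            chrom, a1 = pool.random_bin(margin=200_000)
            span = None
            for _ in range(200):
                cand = _draw_span(cfg, rng)
                if a1 + cand + RES <= cfg.chromosomes[chrom] and pool.take(chrom, a1 + cand):
                    span = cand
                    break
            if span is None:
                for cand in range(30_000, 200_000, RES):
                    if a1 + cand + RES <= cfg.chromosomes[chrom] and pool.take(chrom, a1 + cand):
                        span = cand
                        break
            if span is None:
                raise RuntimeError("could not place decoy anchor")
            cond = CONDITIONS[int(rng.integers(len(CONDITIONS)))]
            decoys.append({
                "key": [chrom, a1, a1 + RES, a1 + span, a1 + span + RES],
                "kind": kind, "condition": cond,
            })
    return loops, routing_pools, decoys


def _write_loop_files(cfg, rng, out_dir: Path, loops, decoys):
    (out_dir / "loops").mkdir(parents=True, exist_ok=True)
    present_idx = {"sham": 0, "rep_6h": 1, "rep_24h": 2}
    for cond in CONDITIONS:
        per_rep: list[list[LoopCall]] = [[] for _ in range(cfg.replicates)]
        for lp in loops:
            if lp["pattern"][present_idx[cond]] != "1":
                continue
            chrom, s1, e1, s2, e2 = lp["key"]
            for rep in range(cfg.replicates):
                per_rep[rep].append(LoopCall(
                    anchor1=GenomicInterval(chrom, s1, e1),
                    anchor2=GenomicInterval(chrom, s2, e2),
                    stats=_make_stats(rng, lp["intent"]),
                    sample_id=f"{cond}_rep{rep + 1}", condition=cond, replicate=rep + 1,
                ))
        for dec in decoys:
            if dec["condition"] != cond:
                continue
            chrom, s1, e1, s2, e2 = dec["key"]
            bad_rep = int(rng.integers(cfg.replicates)) if cfg.replicates > 1 else 0
            for rep in range(cfg.replicates):
                if dec["kind"] == "partial" and rep == cfg.replicates - 1:
                    continue  # absent from the last replicate
                failing = dec["kind"] == "failing" and rep == bad_rep
                per_rep[rep].append(LoopCall(
                    anchor1=GenomicInterval(chrom, s1, e1),
                    anchor2=GenomicInterval(chrom, s2, e2),
                    stats=_make_stats(rng, "intermediate", failing=failing),
                    sample_id=f"{cond}_rep{rep + 1}", condition=cond, replicate=rep + 1,
                ))
        for rep in range(cfg.replicates):
            calls = sorted(per_rep[rep], key=lambda c: c.key)
            write_loop_list(calls, out_dir / "loops" / f"{cond}_rep{rep + 1}.tsv")


def _loop_status(pattern: str) -> str:
    s, h6, h24 = (c == "1" for c in pattern)
    if s:
        return "lost" if not (h6 or h24) else "stable"
    return "gained_6h" if h6 else "gained_24h"


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def enrichment_draws(
    rng: np.random.Generator, n: int, planted_or: float,
    class_p: float = 0.3, base_p: float = 0.25,
) -> list[tuple[bool, bool]]:
    """Bernoulli (in_class, in_stratum) draws with a planted odds ratio.

    Stratum odds for in-class transcripts are ``planted_or`` times the base
    odds ``base_p / (1 - base_p)``, so the population 2x2 table has the
    planted odds ratio exactly and a finite sample estimates it.
    """
    base_odds = base_p / (1 - base_p)
    class_odds = base_odds * planted_or
    p_class_stratum = class_odds / (1 + class_odds)
    out = []
    for _ in range(n):
        in_class = bool(rng.random() < class_p)
        p_str = p_class_stratum if in_class else base_p
        out.append((in_class, bool(rng.random() < p_str)))
    return out


def _tad_status_at(chrom: str, pos: int, planted_tads, tp: str) -> str | None:
    """Status of the domain containing `pos` (condition domains take precedence
    over lost sham domains, matching the pipeline's assignment rule)."""
    for d in planted_tads[tp]["cond"]:
        if d["chrom"] == chrom and d["start"] <= pos < d["end"]:
            return d["status"]
    for d in planted_tads[tp]["lost"]:
        if d["chrom"] == chrom and d["start"] <= pos < d["end"]:
            return "lost"
    return None


def _comp_class_at(chrom: str, pos: int, plan, bin_size: int, tp: str) -> str | None:
    start = (pos // bin_size) * bin_size
    key = {"rep_6h": "class_6h", "rep_24h": "class_24h"}[tp]
    for iv, info in plan.items():
        if iv.chrom == chrom and iv.start == start:
            return info.get(key)
    return None


def _plant_transcripts(cfg, rng, loops, routing_pools, planted_tads, plan):
    """Route transcripts onto loop anchors; plant the enrichment odds ratio.

    Each transcript sits inside exactly one anchor bin (anchors never overlap),
    so its loop membership, TAD status (anchor midpoint) and compartment class
    are fully determined at planting time and recorded in the manifest.
    """
    transcripts: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    tid = 0

    def de_values(direction: str) -> tuple[float, float]:
        if direction == "up":
            return float(rng.uniform(1.2, 4.0)), float(rng.uniform(1e-5, 0.04))
        if direction == "down":
            return -float(rng.uniform(1.2, 4.0)), float(rng.uniform(1e-5, 0.04))
        return float(rng.uniform(-0.5, 0.5)), float(rng.uniform(0.2, 0.9))

    def place_on(loop: dict, direction: str, biotype: str, subpop: str, tp_hint: str | None):
        nonlocal tid
        tid += 1
        chrom, s1, e1, s2, e2 = loop["key"]
        offset = int(rng.integers(0, (e1 - s1 - 2000) // 100 + 1)) * 100
        locus = GenomicInterval(chrom, s1 + offset, s1 + offset + 2000)
        log2_fc, adj_p = de_values(direction)
        rec = TranscriptRecord(
            transcript_id=f"T{tid:05d}", locus=locus, biotype=biotype,
            log2_fc=log2_fc, adj_p=adj_p, direction=direction,
        )
        transcripts.append(rec)
        status = _loop_status(loop["pattern"])
        row = {
            "id": rec.transcript_id, "biotype": biotype, "direction": direction,
            "subpop": subpop, "loop_key": loop["key"], "loop_status": status,
        }
        for tp in TIMEPOINTS:
            row[f"tad_{tp}"] = _tad_status_at(chrom, locus.midpoint, planted_tads, tp)
            row[f"comp_{tp}"] = _comp_class_at(chrom, locus.midpoint, plan, cfg.bin_size, tp)
        if tp_hint:
            row["routed_tp"] = tp_hint
        truth_rows.append(row)

    # --- routed transcripts: multinomial over loop->TAD paths per timepoint
    paths = sorted(cfg.routing_weights)
    weights = np.array([cfg.routing_weights[p] for p in paths], dtype=float)
    weights /= weights.sum()
    routed_counts = {tp: {p: 0 for p in paths} for tp in TIMEPOINTS}
    for tp in TIMEPOINTS:
        draws = rng.choice(len(paths), size=cfg.n_routed_per_tp, p=weights)
        for d in draws:
            path = paths[int(d)]
            routed_counts[tp][path] += 1
            pool_ids = routing_pools[(tp, path)]
            loop = loops[pool_ids[int(rng.integers(len(pool_ids)))]]
            direction = "up" if rng.random() < 0.5 else "down"
            biotype = "noncoding" if rng.random() < 0.5 else "coding"
            place_on(loop, direction, biotype, "routed", tp)

    # --- enrichment population: class = upregulated noncoding; stratum = in a
    # lost loop; stratum odds for the class are planted_or times the base odds
    lost_loops = [lp for lp in loops if lp["pattern"] == "100"]
    stable_loops = [lp for lp in loops if lp["pattern"] == "111"]
    table = {"a": 0, "b": 0, "c": 0, "d": 0}
    for in_class, in_stratum in enrichment_draws(
        rng, cfg.n_enrichment, cfg.planted_or, cfg.enrich_class_p, cfg.enrich_base_p
    ):
        if in_class:
            direction, biotype = "up", "noncoding"
            table["a" if in_stratum else "b"] += 1
        else:
            direction, biotype = [
                ("up", "coding"), ("down", "coding"), ("down", "noncoding"),
                ("ns", "coding"), ("ns", "noncoding"),
            ][int(rng.integers(5))]
            table["c" if in_stratum else "d"] += 1
        host = lost_loops if in_stratum else stable_loops
        place_on(host[int(rng.integers(len(host)))], direction, biotype, "enrichment", None)

    # --- unstructured background off every anchor
    pool = _BinPool(cfg.chromosomes, rng)
    pool.used = {(lp["key"][0], lp["key"][1]) for lp in loops} | \
                {(lp["key"][0], lp["key"][3]) for lp in loops}
    for _ in range(cfg.n_background):
        tid += 1
        chrom, start = pool.random_bin()
        locus = GenomicInterval(chrom, start + 1000, start + 3000)
        log2_fc, adj_p = de_values("ns")
        biotype = "noncoding" if rng.random() < 0.5 else "coding"
        rec = TranscriptRecord(
            transcript_id=f"T{tid:05d}", locus=locus, biotype=biotype,
            log2_fc=log2_fc, adj_p=adj_p, direction="ns",
        )
        transcripts.append(rec)
        row = {"id": rec.transcript_id, "biotype": biotype, "direction": "ns",
               "subpop": "background", "loop_key": None, "loop_status": None}
        for tp in TIMEPOINTS:
            row[f"tad_{tp}"] = _tad_status_at(chrom, locus.midpoint, planted_tads, tp)
            row[f"comp_{tp}"] = _comp_class_at(chrom, locus.midpoint, plan, cfg.bin_size, tp)
        truth_rows.append(row)
    return transcripts, truth_rows, table, routed_counts


# ---------------------------------------------------------------------------
# regulatory elements
# ---------------------------------------------------------------------------

_ELEMENT_WIDTH = {"enhancer": 1000, "promoter": 1000, "ctcf": 200,
                  "super_enhancer": 10_000, "stroke_super_enhancer": 10_000}


def _plant_elements(cfg, rng, planted_tads):
    gained = []
    lost = []
    for tp in TIMEPOINTS:
        gained += [d for d in planted_tads[tp]["cond"] if d["status"] == "gained"]
        lost += planted_tads[tp]["lost"]
    elements: dict[str, list[RegulatoryElement]] = {}
    for cls in sorted(cfg.element_densities):
        dens_gained, dens_lost, n_bg = cfg.element_densities[cls]
        width = _ELEMENT_WIDTH[cls]
        out: list[RegulatoryElement] = []

        def scatter(dom, per_100kb):
            n = rng.poisson(per_100kb * (dom["end"] - dom["start"]) / 100_000)
            for _ in range(int(n)):
                s = int(rng.integers(dom["start"], max(dom["start"] + 1, dom["end"] - width)))
                out.append(RegulatoryElement(
                    interval=GenomicInterval(dom["chrom"], s, s + width), element_class=cls))

        for dom in gained:
            scatter(dom, dens_gained)
        for dom in lost:
            scatter(dom, dens_lost)
        for chrom in sorted(cfg.chromosomes):
            for _ in range(n_bg):
                s = int(rng.integers(1_000_000, cfg.chromosomes[chrom] - width))
                out.append(RegulatoryElement(
                    interval=GenomicInterval(chrom, s, s + width), element_class=cls))
        elements[cls] = out
    return elements


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_dataset(
    out_dir: str | Path,
    seed: int,
    config: SimulationConfig | None = None,
) -> TruthManifest:
    """Write the full synthetic scene under ``out_dir`` and return the manifest.

    Also writes ``config.yaml`` (a ready-to-run pipeline configuration pointing
    at the generated files) and ``truth.json``.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    blacklist = []
    for chrom in sorted(cfg.chromosomes):
        for i in range(cfg.blacklist_bins_per_chrom):
            blacklist.append(GenomicInterval(chrom, i * cfg.bin_size, (i + 1) * cfg.bin_size))
    write_blacklist(blacklist, out_dir / "blacklist.bed")

    bins, retained, plan = _plant_compartments(cfg, rng, blacklist)
    _write_eigen_tracks(cfg, rng, out_dir, bins, retained, plan, blacklist)

    slots = _layout_tad_slots(cfg, rng)
    sham_domains, planted_tads, tad_decoys = _plant_tads(cfg, rng, slots)
    _write_domain_files(cfg, rng, out_dir, sham_domains, planted_tads, tad_decoys)

    pool = _BinPool(cfg.chromosomes, rng)
    loops, routing_pools, loop_decoys = _plant_loops(cfg, rng, pool, planted_tads)
    _write_loop_files(cfg, rng, out_dir, loops, loop_decoys)

    transcripts, transcript_truth, enrich_table, routed_counts = _plant_transcripts(
        cfg, rng, loops, routing_pools, planted_tads, plan
    )
    write_transcripts(transcripts, out_dir / "transcripts.tsv")

    elements = _plant_elements(cfg, rng, planted_tads)
    (out_dir / "elements").mkdir(exist_ok=True)
    for cls in sorted(elements):
        write_bed_elements(elements[cls], out_dir / "elements" / f"{cls}.bed")

    manifest = TruthManifest(data={
        "seed": seed,
        "genome": dict(sorted(cfg.chromosomes.items())),
        "bin_size": cfg.bin_size,
        "replicates": cfg.replicates,
        "blacklist": [[iv.chrom, iv.start, iv.end] for iv in blacklist],
        "compartments": {
            "bins": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "sham": plan[iv]["sham"], "class_rep_6h": plan[iv]["class_6h"],
                 "class_rep_24h": plan[iv]["class_24h"]}
                for iv in retained
            ],
        },
        "domains": {
            "sham": [
                {"chrom": d["chrom"], "start": d["start"], "end": d["end"]}
                for d in sorted(sham_domains, key=lambda d: (d["chrom"], d["start"]))
            ],
            "decoys": tad_decoys,
            "by_timepoint": {
                tp: {
                    "cond": sorted(planted_tads[tp]["cond"],
                                   key=lambda d: (d["chrom"], d["start"])),
                    "lost": sorted(planted_tads[tp]["lost"],
                                   key=lambda d: (d["chrom"], d["start"])),
                }
                for tp in TIMEPOINTS
            },
        },
        "loops": {
            "universe": [
                {"key": lp["key"], "pattern": lp["pattern"], "intent": lp["intent"],
                 "status": _loop_status(lp["pattern"])}
                for lp in sorted(loops, key=lambda l: tuple(l["key"]))
            ],
            "decoys": loop_decoys,
        },
        "transcripts": transcript_truth,
        "enrichment": {
            "planted_or": cfg.planted_or,
            "class": "up:noncoding",
            "stratum": "lost_loop",
            "table": enrich_table,
        },
        "routing": {"weights": cfg.routing_weights, "counts": routed_counts},
    })
    manifest.save(out_dir / "truth.json")
    _write_pipeline_config(cfg, out_dir)
    return manifest


def _write_pipeline_config(cfg: SimulationConfig, out_dir: Path) -> None:
    """Emit a ready-to-run pipeline config (plain YAML, written by hand so the
    file is byte-stable)."""
    lines = ["inputs:"]
    for kind, sub in (("eigenvector", "eigen"), ("domains", "domains"), ("loops", "loops")):
        lines.append(f"  {kind}:")
        for cond in CONDITIONS:
            paths = ", ".join(
                f"{sub}/{cond}_rep{r}.{'bedgraph' if sub == 'eigen' else 'tsv'}"
                for r in range(1, cfg.replicates + 1)
            )
            lines.append(f"    {cond}: [{paths}]")
    lines += [
        "  gene_density: gene_density.bedgraph",
        "  blacklist: blacklist.bed",
        "  transcripts: transcripts.tsv",
        "  elements:",
    ]
    for cls in sorted(cfg.element_densities):
        lines.append(f"    {cls}: elements/{cls}.bed")
    lines += [
        "thresholds:",
        "  ro_min: 0.8",
        "  stable_tol: 10000",
        "  consensus_tol: 20000",
        "  fusion_tol: 40000",
        "  loop_pass_adj_p: 0.05",
        "  loop_pass_min_count: 3",
        "  loop_strong_obs: 15",
        "  loop_strong_oe: 2.5",
        "  loop_strong_adj_p: 0.05",
        "  loop_weak_obs: 10",
        "  loop_weak_oe: 1.5",
        "  short_long_cut: 200000",
        "  boundary_strong_z: 1.0",
        "  de_adj_p: 0.05",
        "  de_abs_log2fc: 1.0",
        "modes:",
        "  lost_loops: strict",
        "  enrichment_universe: all_located",
        f"bin_size: {cfg.bin_size}",
        "seed: 0",
    ]
    (out_dir / "config.yaml").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# corruption modes for reader error-path tests
# ---------------------------------------------------------------------------

CORRUPTION_MODES = ("interchromosomal_loop", "overlapping_bins", "nan_eigen",
                    "off_resolution_anchor")


def corrupt_dataset(tree: str | Path, mode: str, out: str | Path | None = None) -> Path:
    """Copy a generated scene and apply one named corruption to it."""
    tree = Path(tree)
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    dest = Path(out) if out is not None else tree.parent / f"{tree.name}_{mode}"
    if dest.exists():
        shutil.rmtree(dest)
    shutil.copytree(tree, dest)
    loop_file = dest / "loops" / "sham_rep1.tsv"
    eigen_file = dest / "eigen" / "sham_rep1.bedgraph"
    if mode == "interchromosomal_loop":
        with open(loop_file) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        stats = "\t".join(["5"] * 4 + ["1.2"] * 4 + ["0.5"] * 4)
        with open(loop_file, "a") as fh:
            fh.write(f"chr1\t5000000\t5010000\tchr2\t7000000\t7010000\t{stats}\n")
        assert len(header) == 18
    elif mode == "overlapping_bins":
        lines = eigen_file.read_text().splitlines()
        chrom, start, end, _ = lines[0].split("\t")
        lines.insert(1, f"{chrom}\t{int(start) + 1000}\t{int(end) + 1000}\t0.1")
        eigen_file.write_text("\n".join(lines) + "\n")
    elif mode == "nan_eigen":
        lines = eigen_file.read_text().splitlines()
        parts = lines[0].split("\t")
        parts[3] = "nan"
        lines[0] = "\t".join(parts)
        eigen_file.write_text("\n".join(lines) + "\n")
    else:  # off_resolution_anchor
        stats = "\t".join(["5"] * 4 + ["1.2"] * 4 + ["0.5"] * 4)
        with open(loop_file, "a") as fh:
            fh.write(f"chr1\t5000000\t5007000\tchr1\t7000000\t7010000\t{stats}\n")
    return dest
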
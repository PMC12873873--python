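"""End-to-end orchestration: compartments -> TADs -> loops -> integration.

``run_all`` validates the configuration fail-fast, executes the four stages
in order, writes one TSV per stage output with a stable column order, and
returns all in-memory results for programmatic use.  Every stage logs its
record-count accounting (in, out, dropped) so conservation invariants are
auditable, and the whole run is deterministic: fixed inputs and config give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import compartments as comp
from . import domains as dom
from . import integration as integ
from . import loops as lps
from .config import PipelineConfig
from .intervals import GenomicInterval
from .io import (
    CONDITIONS,
    read_bed_elements,
    read_blacklist,
    read_domain_list,
    read_eigenvector_bedgraph,
    read_loop_list,
    read_transcripts,
)

logger = logging.getLogger(__name__)

TIMEPOINTS = ("rep_6h", "rep_24h")

__all__ = ["run_all", "summarize", "PipelineResults"]


@dataclass
class PipelineResults:
    compartment_classes: dict  # tp -> list[CompartmentClass]
    class_fractions: dict  # tp -> {class: fraction}
    consensus_domains: dict  # condition -> list[ConsensusDomain]
    domain_statuses: dict  # tp -> list[DomainStatus]
    reproducible_loops: dict  # condition -> list[ReproducibleLoop]
    loop_deltas: list  # list[LoopDelta]
    annotated: dict  # tp -> list[AnnotatedTranscript]
    enrichment: dict  # (tp, layer) -> list[EnrichmentResult]
    flows: dict  # tp -> list[FlowRecord]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class _Anchored:
    anchor1: GenomicInterval
    anchor2: GenomicInterval


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_compartments(cfg: PipelineConfig, out_dir: Path | None = None):
    blacklist = read_blacklist(cfg.resolve(cfg.blacklist)) if cfg.blacklist else []
    density = read_eigenvector_bedgraph(cfg.resolve(cfg.gene_density), sample_id="gene_density")
    labels: dict[str, dict] = {}
    for cond in CONDITIONS:
        rep_bins = []
        for i, path in enumerate(cfg.eigenvector[cond], start=1):
            track = read_eigenvector_bedgraph(
                cfg.resolve(path), sample_id=f"{cond}_rep{i}", condition=cond,
                replicate=i, bin_size=cfg.bin_size, blacklist=blacklist,
            )
            rep_bins.append(comp.orient_labels(comp.zscore_track(track), density))
        labels[cond] = comp.condition_consensus(rep_bins)
    classes = {
        tp: comp.classify_switches(labels["sham"], labels[tp], tp) for tp in TIMEPOINTS
    }
    fractions = {tp: comp.class_fractions(classes[tp]) for tp in TIMEPOINTS}
    if out_dir:
        for tp in TIMEPOINTS:
            df = pd.DataFrame(
                [
                    {
                        "chrom": c.interval.chrom, "start": c.interval.start,
                        "end": c.interval.end, "sham_label": c.sham_label,
                        "cond_label": c.condition_label, "switch_class": c.switch_class,
                    }
                    for c in classes[tp]
                ]
            )
            _write_tsv(df, out_dir / f"compartment_classes_{tp}.tsv")
    return classes, fractions


def stage_domains(cfg: PipelineConfig, out_dir: Path | None = None):
    blacklist = read_blacklist(cfg.resolve(cfg.blacklist)) if cfg.blacklist else []
    t = cfg.thresholds
    consensus: dict[str, list] = {}
    for cond in CONDITIONS:
        reps = [
            read_domain_list(
                cfg.resolve(p), sample_id=f"{cond}_rep{i}", condition=cond,
                replicate=i, blacklist=blacklist,
            )
            for i, p in enumerate(cfg.domains[cond], start=1)
        ]
        consensus[cond] = dom.consensus_domains(reps, tolerance=t["consensus_tol"], condition=cond)
        logger.info("%s: %d consensus TADs from %d replicates", cond, len(consensus[cond]), len(reps))
    elements = _load_elements(cfg)
    statuses: dict[str, list] = {}
    for tp in TIMEPOINTS:
        st = dom.compare_to_sham(
            consensus["sham"], consensus[tp], ro_min=t["ro_min"], stable_tol=t["stable_tol"]
        )
        st = dom.detect_fusion_fission(consensus["sham"], consensus[tp], st, tolerance=t["fusion_tol"])
        st = dom.stratify_domains(st, strong_z=t["boundary_strong_z"])
        statuses[tp] = st
        if out_dir:
            rows = []
            for s in st:
                iv = s.domain.interval
                rows.append({
                    "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "side": "sham" if s.status == "lost" else "condition",
                    "status": s.status, "category2": s.category2,
                    "derived_from_split": s.derived_from_split,
                    "length_class": s.length_class, "strength_class": s.strength_class,
                    "boundary_score": s.domain.boundary_score,
                    "matched_start": s.partner.start if s.partner else -1,
                    "matched_end": s.partner.end if s.partner else -1,
                })
            _write_tsv(pd.DataFrame(rows), out_dir / f"tad_status_{tp}.tsv")
            dens = dom.domain_element_density(st, elements)
            for row, s in zip(dens, st):
                row["status"] = s.status
            _write_tsv(pd.DataFrame(dens), out_dir / f"tad_density_{tp}.tsv")
    return consensus, statuses


def _load_elements(cfg: PipelineConfig):
    elements = []
    for cls in sorted(cfg.elements):
        elements.extend(read_bed_elements(cfg.resolve(cfg.elements[cls]), cls))
    return elements


def stage_loops(cfg: PipelineConfig, consensus_tads: dict, out_dir: Path | None = None):
    t = cfg.thresholds
    reproducible: dict[str, list] = {}
    for cond in CONDITIONS:
        reps = [
            read_loop_list(cfg.resolve(p), sample_id=f"{cond}_rep{i}", condition=cond, replicate=i)
            for i, p in enumerate(cfg.loops[cond], start=1)
        ]
        reproducible[cond] = lps.reproducible_loops(
            reps, condition=cond,
            adj_p_max=t["loop_pass_adj_p"], min_count=t["loop_pass_min_count"],
            strong_obs=t["loop_strong_obs"], strong_oe=t["loop_strong_oe"],
            strong_adj_p=t["loop_strong_adj_p"], weak_obs=t["loop_weak_obs"],
            weak_oe=t["loop_weak_oe"], length_cut=t["short_long_cut"],
        )
        logger.info("%s: %d reproducible loops", cond, len(reproducible[cond]))
    deltas = lps.diff_loops(reproducible["sham"], reproducible["rep_6h"], reproducible["rep_24h"])
    by_key = {}
    for cond in CONDITIONS:
        for lp in reproducible[cond]:
            by_key.setdefault(lp.key, lp)
    if out_dir:
        elements = _load_elements(cfg)
        rows = []
        for d in deltas:
            chrom, s1, e1, s2, e2 = d.key
            ref = by_key[d.key]
            loop_obj = _Anchored(GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2))
            row = {
                "chrom": chrom, "start1": s1, "end1": e1, "start2": s2, "end2": e2,
                "span": s2 - s1, "status": d.status,
                "lost_6h": d.lost_6h, "lost_24h": d.lost_24h,
                "in_sham": d.in_sham, "in_6h": d.in_6h, "in_24h": d.in_24h,
                "strength": ref.strength,
                "length_class": lps.classify_length(s2 - s1, t["short_long_cut"]),
            }
            for cond in CONDITIONS:
                row[f"context_{cond}"] = lps.loop_tad_context(loop_obj, consensus_tads[cond])
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), out_dir / "loops_status.tsv")
        for cond in CONDITIONS:
            dens = lps.anchor_element_density(reproducible[cond], elements)
            _write_tsv(pd.DataFrame(dens), out_dir / f"loop_anchor_density_{cond}.tsv")
    return reproducible, deltas


def stage_integration(
    cfg: PipelineConfig,
    deltas,
    domain_statuses: dict,
    compartment_classes: dict,
    out_dir: Path | None = None,
):
    t = cfg.thresholds
    transcripts = read_transcripts(
        cfg.resolve(cfg.transcripts),
        fc_threshold=t["de_abs_log2fc"], p_threshold=t["de_adj_p"],
    )
    annotated: dict[str, list] = {}
    enrichment: dict[tuple, list] = {}
    flows: dict[str, list] = {}
    for tp in TIMEPOINTS:
        ann = integ.assign_transcripts(
            transcripts, deltas, domain_statuses[tp], compartment_classes[tp], tp
        )
        annotated[tp] = ann
        for layer in ("loop", "tad", "compartment"):
            enrichment[(tp, layer)] = integ.enrichment_tables(
                ann, layer, universe=cfg.modes["enrichment_universe"]
            )
        flows[tp] = integ.sankey_flows(ann, timepoint=tp, include_compartment=True)
        if out_dir:
            for layer in ("loop", "tad", "compartment"):
                rows = [
                    {
                        "stratum": r.stratum, "a": r.table.a, "b": r.table.b,
                        "c": r.table.c, "d": r.table.d, "odds_ratio": r.odds_ratio,
                        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "adj_p": r.adj_p,
                    }
                    for r in enrichment[(tp, layer)]
                ]
                _write_tsv(pd.DataFrame(rows), out_dir / f"enrichment_{layer}_{tp}.tsv")
            _write_tsv(
                pd.DataFrame([
                    {"stratum": f.stratum, "path": f.path, "count": f.count,
                     "percent": f.percent_of_stratum}
                    for f in flows[tp]
                ]),
                out_dir / f"flows_{tp}.tsv",
            )
            two_level = integ.sankey_flows(ann, timepoint=tp, include_compartment=False)
            _write_tsv(
                pd.DataFrame([
                    {"stratum": f.stratum, "path": f.path, "count": f.count,
                     "percent": f.percent_of_stratum}
                    for f in two_level
                ]),
                out_dir / f"flows_looptad_{tp}.tsv",
            )
    return annotated, enrichment, flows


def _wilcoxon_comparisons(results: PipelineResults, out_dir: Path) -> None:
    """Distribution comparisons: boundary strength and loop span, per timepoint."""
    rows = []
    for tp in TIMEPOINTS:
        gained = [s.domain.boundary_score for s in results.domain_statuses[tp] if s.status == "gained"]
        lost = [s.domain.boundary_score for s in results.domain_statuses[tp] if s.status == "lost"]
        if gained and lost:
            stat, p = integ.wilcoxon_rank_sum(gained, lost)
            rows.append({"comparison": f"boundary_score_gained_vs_lost_{tp}",
                         "n_x": len(gained), "n_y": len(lost), "statistic": stat, "p": p})
        spans_tp = [l.span for l in results.reproducible_loops[tp]]
        spans_sham = [l.span for l in results.reproducible_loops["sham"]]
        if spans_tp and spans_sham:
            stat, p = integ.wilcoxon_rank_sum(spans_tp, spans_sham)
            rows.append({"comparison": f"loop_span_{tp}_vs_sham",
                         "n_x": len(spans_tp), "n_y": len(spans_sham), "statistic": stat, "p": p})
    if rows:
        _write_tsv(pd.DataFrame(rows), out_dir / "wilcoxon_comparisons.tsv")


# ---------------------------------------------------------------------------
# run-all and summary
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResults:
    """Execute all stages in order; fail-fast before writing anything."""
    cfg.validate(check_paths=True)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classes, fractions = stage_compartments(cfg, out_dir)
    consensus, statuses = stage_domains(cfg, out_dir)
    reproducible, deltas = stage_loops(cfg, consensus, out_dir)
    annotated, enrichment, flows = stage_integration(cfg, deltas, statuses, classes, out_dir)
    results = PipelineResults(
        compartment_classes=classes, class_fractions=fractions,
        consensus_domains=consensus, domain_statuses=statuses,
        reproducible_loops=reproducible, loop_deltas=deltas,
        annotated=annotated, enrichment=enrichment, flows=flows,
    )
    _wilcoxon_comparisons(results, out_dir)
    summarize(out_dir)
    return results


def summarize(out_dir: str | Path) -> pd.DataFrame:
    """Aggregate stage TSVs into summary.tsv and a readable summary.txt."""
    out_dir = Path(out_dir)
    rows: list[dict] = []
    lines: list[str] = []

    for tp in TIMEPOINTS:
        path = out_dir / f"compartment_classes_{tp}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            n = len(df)
            lines.append(f"[{tp}] compartment bins classified: {n}")
            for cls in ("StableA", "StableB", "AtoB", "BtoA"):
                frac = (df["switch_class"] == cls).mean() if n else 0.0
                rows.append({"section": "compartments", "timepoint": tp,
                             "metric": f"fraction_{cls}", "value": round(float(frac), 6)})
                lines.append(f"    {cls}: {100 * frac:.1f}%")
        else:
            lines.append(f"[{tp}] compartment section absent")

        path = out_dir / f"tad_status_{tp}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            for status in ("stable", "shifted", "gained", "lost"):
                count = int((df["status"] == status).sum())
                rows.append({"section": "tads", "timepoint": tp,
                             "metric": f"count_{status}", "value": count})
            n_merged = int((df["category2"] == "merged").sum())
            n_split = int((df["category2"] == "split").sum())
            rows.append({"section": "tads", "timepoint": tp, "metric": "count_merged", "value": n_merged})
            rows.append({"section": "tads", "timepoint": tp, "metric": "count_split", "value": n_split})
            lines.append(
                f"[{tp}] TADs: " + ", ".join(
                    f"{s}={int((df['status'] == s).sum())}" for s in ("stable", "shifted", "gained", "lost")
                ) + f", merged={n_merged}, split={n_split}"
            )
        else:
            lines.append(f"[{tp}] TAD section absent")

    path = out_dir / "loops_status.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t")
        if len(df):
            for status in ("stable", "gained_6h", "gained_24h", "lost"):
                count = int((df["status"] == status).sum())
                rows.append({"section": "loops", "timepoint": "all",
                             "metric": f"count_{status}", "value": count})
            lines.append(
                "[loops] union=" + str(len(df)) + ", " + ", ".join(
                    f"{s}={int((df['status'] == s).sum())}"
                    for s in ("stable", "gained_6h", "gained_24h", "lost")
                )
            )
        else:
            lines.append("[loops] section absent (empty loop table)")
    else:
        lines.append("[loops] section absent")

    for tp in TIMEPOINTS:
        path = out_dir / f"enrichment_loop_{tp}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            if len(df):
                top = df.sort_values(["adj_p", "stratum"]).iloc[0]
                rows.append({"section": "enrichment", "timepoint": tp,
                             "metric": f"top_loop_stratum:{top['stratum']}",
                             "value": round(float(top["odds_ratio"]), 6)})
                lines.append(
                    f"[{tp}] top loop enrichment: {top['stratum']} "
                    f"OR={top['odds_ratio']:.2f} adj.p={top['adj_p']:.3g}"
                )

    summary = pd.DataFrame(rows, columns=["section", "timepoint", "metric", "value"])
    _write_tsv(summary, out_dir / "summary.tsv")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
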
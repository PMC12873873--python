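"""Structured pipeline configuration.

Every numeric threshold of the analysis lives here under a named key with the
published value as its default (reciprocal overlap 0.8, stable tolerance
10 kb, consensus tolerance 20 kb, fusion tolerance 40 kb, loop pass rule
adj p < 0.05 with >= 3 observed contacts, strong/weak loop cuts, 200 kb
short/long split, boundary-strength z > 1, DE cutoffs), so any deviation is
visible in the config file rather than buried in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import CONDITIONS, ELEMENT_CLASSES

__all__ = ["PipelineConfig", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {
    "ro_min": 0.8,
    "stable_tol": 10_000,
    "consensus_tol": 20_000,
    "fusion_tol": 40_000,
    "loop_pass_adj_p": 0.05,
    "loop_pass_min_count": 3,
    "loop_strong_obs": 15,
    "loop_strong_oe": 2.5,
    "loop_strong_adj_p": 0.05,
    "loop_weak_obs": 10,
    "loop_weak_oe": 1.5,
    "short_long_cut": 200_000,
    "boundary_strong_z": 1.0,
    "de_adj_p": 0.05,
    "de_abs_log2fc": 1.0,
}

DEFAULT_MODES = {
    "lost_loops": "strict",  # or "per_timepoint"
    "enrichment_universe": "all_located",  # or "all_expressed"
}


@dataclass
class PipelineConfig:
    base_dir: Path
    eigenvector: dict  # condition -> list of paths
    domains: dict
    loops: dict
    gene_density: str
    transcripts: str
    elements: dict  # element class -> path
    blacklist: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    modes: dict = field(default_factory=lambda: dict(DEFAULT_MODES))
    bin_size: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds", {}))
        modes = dict(DEFAULT_MODES)
        modes.update(raw.get("modes", {}))
        cfg = cls(
            base_dir=path.parent,
            eigenvector=inputs.get("eigenvector", {}),
            domains=inputs.get("domains", {}),
            loops=inputs.get("loops", {}),
            gene_density=inputs.get("gene_density", ""),
            transcripts=inputs.get("transcripts", ""),
            elements=inputs.get("elements", {}),
            blacklist=inputs.get("blacklist"),
            thresholds=thresholds,
            modes=modes,
            bin_size=int(raw.get("bin_size", 1_000_000)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self, check_paths: bool = False) -> None:
        t = self.thresholds
        if not (0 < t["ro_min"] <= 1):
            raise ValueError(f"ro_min must lie in (0, 1], got {t['ro_min']}")
        for key in ("stable_tol", "consensus_tol", "fusion_tol", "short_long_cut",
                    "loop_pass_min_count"):
            if t[key] <= 0:
                raise ValueError(f"threshold {key} must be positive")
        for key in ("loop_pass_adj_p", "loop_strong_adj_p", "de_adj_p"):
            if not (0 < t[key] <= 1):
                raise ValueError(f"threshold {key} must lie in (0, 1]")
        if self.modes["lost_loops"] not in ("strict", "per_timepoint"):
            raise ValueError(f"unknown lost_loops mode {self.modes['lost_loops']!r}")
        if self.modes["enrichment_universe"] not in ("all_located", "all_expressed"):
            raise ValueError(
                f"unknown enrichment_universe {self.modes['enrichment_universe']!r}")
        for cls in self.elements:
            if cls not in ELEMENT_CLASSES:
                raise ValueError(f"unknown element class {cls!r}")
        if check_paths:
            missing = []
            for cond in CONDITIONS:
                for kind in (self.eigenvector, self.domains, self.loops):
                    for p in kind.get(cond, []):
                        if not self.resolve(p).exists():
                            missing.append(p)
            for p in [self.gene_density, self.transcripts, *self.elements.values()]:
                if p and not self.resolve(p).exists():
                    missing.append(p)
            if self.blacklist and not self.resolve(self.blacklist).exists():
                missing.append(self.blacklist)
            if missing:
                raise FileNotFoundError(f"missing input file(s): {missing}")
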
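"""Pipeline configuration: every tunable in one validated, serialisable place.

Defaults reproduce the published operating point of the system: K = 35
clusters, IC threshold 80%, 5 CSP projections per class, the 8-12 / 12-20 /
20-30 Hz sub-bands, and a 10% FPR bound for grid selection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .hierarchy import DEFAULT_K_GRID, DEFAULT_T_GRID


@dataclass
class PipelineConfig:
    # epoching
    ic_window: tuple = (4.0, 7.0)
    nc_window: tuple = (0.0, 2.0)
    nc_fraction: float = 2.0 / 3.0
    # filters
    broadband: tuple = (1.0, 50.0)
    broadband_order: int = 10
    notch: float = 50.0
    notch_q: float = 30.0
    bands: tuple = ((8.0, 12.0), (12.0, 20.0), (20.0, 30.0))
    band_order: int = 4
    # CSP
    n_keep: int = 5
    csp_shrinkage: float = 1e-5
    # feature selection
    cfs_measure: str = "pearson"
    cfs_stall: int = 5
    # level 1 / grid
    k: int = 35
    ic_threshold: float = 0.8
    k_grid: tuple = DEFAULT_K_GRID
    t_grid: tuple = DEFAULT_T_GRID
    fpr_bound: float = 0.10
    assignment_rule: str = "average"
    kmeans_restarts: int = 10
    # level 2
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    variant: str = "four"          # "four" | "five"
    # protocol
    n_runs: int = 5
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.ic_threshold <= 1:
            raise ValueError("ic_threshold must be in (0, 1]")
        if not 0 < self.nc_fraction <= 1:
            raise ValueError("nc_fraction must be in (0, 1]")
        if not 0 < self.fpr_bound < 1:
            raise ValueError("fpr_bound must be in (0, 1)")
        if self.variant not in ("four", "five"):
            raise ValueError("variant must be 'four' or 'five'")
        if self.assignment_rule not in ("average", "centroid"):
            raise ValueError("assignment_rule must be 'average' or 'centroid'")
        for w in (self.ic_window, self.nc_window, self.broadband,
                  *self.bands):
            if not w[0] < w[1]:
                raise ValueError(f"bad window/band {w}")
        if self.n_keep < 1 or self.n_runs < 1 or self.n_folds < 2:
            raise ValueError("n_keep/n_runs/n_folds out of range")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("ic_window", "nc_window", "broadband", "k_grid",
                    "t_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [[float(x) for x in b] for b in self.bands]
        for key in ("ic_window", "nc_window", "broadband", "t_grid"):
            d[key] = [float(x) for x in d[key]]
        d["k_grid"] = [int(x) for x in d["k_grid"]]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
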
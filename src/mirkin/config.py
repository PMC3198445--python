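"""Campaign configuration.

Every constant the method leaves open (validation threshold, binding-site
bound, factor-grid resolution, search budget, solver variant) lives here,
never in code, and can be loaded from a flat YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["CampaignConfig"]


@dataclass(frozen=True)
class CampaignConfig:
    #: validation threshold on ErrPred, percent (strict inequality)
    threshold: float = 10.0
    #: upper bound on Hill binding-site counts
    c_max: int = 4
    #: coarse grid on the saturating factor a/(1+a) in (0, 1)
    factor_grid: tuple[float, ...] = tuple(round(0.1 * i, 2) for i in range(1, 10))
    #: multi-scale refinement: levels, half-width and step around the incumbent
    refinement_levels: int = 1
    refine_halfwidth: float = 0.05
    refine_step: float = 0.01
    #: largest miRNA subset in a translation-inhibition architecture
    max_combo: int = 3
    #: subset cap for proteins recorded in a single condition (e.g. GCNF)
    max_combo_single_condition: int = 1
    #: rate solver: nonnegative least squares or L1 linear program
    rate_solver: str = "nnls"  # "nnls" | "l1_lp"
    #: global ErrPred aggregation over grid points
    errpred_aggregation: str = "mean"  # "mean" | "rms"
    #: candidate search: exhaustive product, coordinate descent, or automatic
    search: str = "auto"  # "auto" | "exhaustive" | "coordinate"
    #: exhaustive-product candidate budget before auto falls back
    budget: int = 2000
    #: coordinate-descent sweep cap
    max_sweeps: int = 3
    #: RK4 substeps per grid interval
    substeps: int = 10
    #: estimate the protein decay rate separately per condition
    condition_specific_kdegp: bool = False

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")
        if self.max_combo < 1:
            raise ValueError("max_combo must be >= 1")
        if not all(0.0 < f < 1.0 for f in self.factor_grid):
            raise ValueError("factor grid must lie strictly inside (0, 1)")
        if self.rate_solver not in ("nnls", "l1_lp"):
            raise ValueError(f"unknown rate solver {self.rate_solver!r}")
        if self.search not in ("auto", "exhaustive", "coordinate"):
            raise ValueError(f"unknown search mode {self.search!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "factor_grid" in raw:
            raw["factor_grid"] = tuple(raw["factor_grid"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["factor_grid"] = list(raw["factor_grid"])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
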
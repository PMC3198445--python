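"""Chemical-kinetics forward models for the two repression architectures.

Transcription–degradation (TD), for the mRNA level G(t) of a gene regulated
by repressor proteins y_j(t), activator proteins y_l(t) and a degrading
miRNA M(t)::

    dG/dt = k_transcr * F(t) - k_react * G * M(t) - k_deg * G

where each regulator protein contributes a Hill-type impact
a = (gamma * y)^c, the synthetic impacts are REP = sum over repressors and
ACT = sum over activators, and the fraction of DNA templates committed to
transcription is::

    F = ACT / ((1 + ACT) * (1 + REP))   (with activators)
    F = 1 / (1 + REP)                   (without activators)

Translation–inhibition (TI), for the protein level P(t) translated from
mRNA G(t) under miRNAs z_i(t)::

    dP/dt = k_transl * G(t) / (1 + REP_mir(t)) - k_degP * P

with REP_mir the summed Hill impacts of the miRNAs; 1/(1+REP_mir) is the
fraction of G committed to translation.

Both equations are scale invariant: rescaling every upstream level x -> s*x
with gamma -> gamma/s (and k_react -> k_react/s) leaves the predicted
downstream trajectory unchanged, which is what makes fits to intensity data
in arbitrary units meaningful.

Integration is explicit 4th-order Runge-Kutta at step 1/30 day (10 substeps
per grid interval), with upstream levels evaluated from their PCHIP
interpolants at the substep times.  At these rate scales the equations are
not stiff, and a fixed-step deterministic scheme keeps the whole campaign
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .architectures import TranscrDegrArch, TranslInhibArch
from .errors import ClampError, DependencyError
from .profiles import Profile, TimeGrid

__all__ = [
    "HillParams",
    "TDParams",
    "TIParams",
    "hill_impact",
    "saturating_factor",
    "synthetic_impacts",
    "committed_fraction",
    "transcr_degr_rhs",
    "transl_inhib_rhs",
    "predict_downstream",
    "SUBSTEPS",
]

#: RK4 substeps per grid interval (step 1/30 day).
SUBSTEPS = 10

#: largest transient negative excursion tolerated as round-off before the
#: integration is considered invalid
CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class HillParams:
    """Hill regulation of one regulator: c binding sites, affinity gamma."""

    c: int
    gamma: float

    def __post_init__(self):
        if self.c < 1:
            raise ValueError("binding-site count c must be >= 1")
        if self.gamma < 0:
            raise ValueError("affinity gamma must be nonnegative")


@dataclass(frozen=True)
class TDParams:
    """Parameters of one transcription-degradation equation.

    ``hill`` maps each regulator protein id to its Hill parameters; rates are
    the transcription rate k_transcr (intensity/day), the miRNA reaction rate
    k_react (1/(intensity day)) and the first-order decay k_deg (1/day).
    """

    hill: Mapping[str, HillParams]
    k_transcr: float
    k_react: float
    k_deg: float

    def __post_init__(self):
        if min(self.k_transcr, self.k_react, self.k_deg) < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def n_params(self) -> int:
        return 2 * len(self.hill) + 3


@dataclass(frozen=True)
class TIParams:
    """Parameters of one translation-inhibition equation.

    ``hill`` maps each miRNA id to its Hill parameters.  The protein decay
    rate k_degP is pre-estimated from the protein's own declining profile and
    is not a fitted unknown; ``k_degP_ko`` optionally holds a separate KO
    estimate (condition-specific protein half-life).
    """

    hill: Mapping[str, HillParams]
    k_transl: float
    k_degP: float
    k_degP_ko: float | None = None

    def __post_init__(self):
        if self.k_transl < 0 or self.k_degP < 0:
            raise ValueError("rates must be nonnegative")

    def decay_for(self, condition) -> float:
        if self.k_degP_ko is not None and getattr(condition, "value", condition) == "KO":
            return self.k_degP_ko
        return self.k_degP

    @property
    def n_params(self) -> int:
        # k_degP is pre-estimated, not fitted
        return 2 * len(self.hill) + 1


def hill_impact(level: float, hp: HillParams) -> float:
    """Individual Hill impact a = (gamma * level)^c of one regulator."""
    if np.any(np.asarray(level) < 0):
        raise ValueError("regulator level must be nonnegative")
    return (hp.gamma * level) ** hp.c


def saturating_factor(impact: float) -> float:
    """Map an impact a to the bounded occupancy factor a / (1 + a) in [0, 1)."""
    return impact / (1.0 + impact)


def synthetic_impacts(
    rep_levels: Sequence[float],
    rep_hill: Sequence[HillParams],
    act_levels: Sequence[float],
    act_hill: Sequence[HillParams],
) -> tuple[float, float]:
    """Aggregate impacts REP and ACT: sums of individual Hill impacts."""
    if len(rep_levels) != len(rep_hill) or len(act_levels) != len(act_hill):
        raise ValueError("levels and Hill parameters must be aligned")
    rep = sum(hill_impact(x, hp) for x, hp in zip(rep_levels, rep_hill))
    act = sum(hill_impact(x, hp) for x, hp in zip(act_levels, act_hill))
    return float(rep), float(act)


def committed_fraction(rep: float, act: float, has_activators: bool) -> float:
    """Fraction of DNA templates committed to transcription.

    With activators F = ACT/((1+ACT)(1+REP)); without, F = 1/(1+REP).
    F is in [0, 1], decreasing in REP and increasing in ACT.
    """
    if rep < 0 or act < 0:
        raise ValueError("impacts must be nonnegative")
    if has_activators:
        return act / ((1.0 + act) * (1.0 + rep))
    return 1.0 / (1.0 + rep)


def transcr_degr_rhs(G: float, M: float, F: float, p: TDParams) -> float:
    """dG/dt of the TD equation at instantaneous levels G, M and fraction F."""
    return p.k_transcr * F - p.k_react * G * M - p.k_deg * G


def transl_inhib_rhs(P: float, G: float, rep_mir: float, p: TIParams, k_degP: float | None = None) -> float:
    """dP/dt of the TI equation at instantaneous levels P, G and impact REP."""
    kd = p.k_degP if k_degP is None else k_degP
    return p.k_transl * G / (1.0 + rep_mir) - kd * P


# ---------------------------------------------------------------------------
# integration


def _fine_times(grid: TimeGrid, substeps: int) -> np.ndarray:
    """Sample times at half-substep resolution (RK4 needs midpoints)."""
    n = (len(grid) - 1) * substeps * 2
    return np.linspace(grid.points[0], grid.points[-1], n + 1)


def _upstream_fine(profile_values: np.ndarray, grid: TimeGrid, substeps: int) -> np.ndarray:
    interp = PchipInterpolator(grid.array, profile_values)
    return np.maximum(interp(_fine_times(grid, substeps)), 0.0)


def integrate_linear_rk4(
    alpha: np.ndarray, beta: np.ndarray, y0: float, dt_half: float, substeps: int
) -> np.ndarray:
    """RK4 for dy/dt = alpha(t) - beta(t) * y with alpha/beta sampled at
    half-substep resolution; returns y at every grid point.

    Both model equations reduce to this linear time-varying form once the
    upstream trajectories are fixed, so the one integrator serves both.
    """
    h = 2.0 * dt_half
    n_half = len(alpha) - 1
    alpha = np.asarray(alpha, dtype=float).tolist()  # scalar loop: plain floats
    beta = np.asarray(beta, dtype=float).tolist()
    y = float(y0)
    out = [y]
    worst_clamp = 0.0
    for i in range(0, n_half, 2):
        a0, a1, a2 = alpha[i], alpha[i + 1], alpha[i + 2]
        b0, b1, b2 = beta[i], beta[i + 1], beta[i + 2]
        k1 = a0 - b0 * y
        k2 = a1 - b1 * (y + 0.5 * h * k1)
        k3 = a1 - b1 * (y + 0.5 * h * k2)
        k4 = a2 - b2 * (y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if y < 0.0:
            worst_clamp = max(worst_clamp, -y)
            y = 0.0
        if (i // 2 + 1) % substeps == 0:
            out.append(y)
    if worst_clamp > CLAMP_TOL:
        raise ClampError(f"negative state excursion {worst_clamp:.3e} exceeds tolerance")
    return np.asarray(out)


def td_alpha_beta(
    arch: TranscrDegrArch,
    params: TDParams,
    upstream_fine: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble alpha(t) = k_transcr*F(t), beta(t) = k_react*M(t) + k_deg."""
    rep = 0.0
    for pid in arch.rep_proteins:
        rep = rep + hill_impact(upstream_fine[pid], params.hill[pid])
    act = 0.0
    for pid in arch.act_proteins:
        act = act + hill_impact(upstream_fine[pid], params.hill[pid])
    if arch.act_proteins:
        F = act / ((1.0 + act) * (1.0 + rep))
    else:
        F = 1.0 / (1.0 + rep)
    F = F * np.ones_like(next(iter(upstream_fine.values())) if upstream_fine else np.zeros(1))
    M = 0.0
    for mid in arch.mirnas:
        M = M + upstream_fine[mid]
    alpha = params.k_transcr * np.asarray(F, dtype=float)
    beta = params.k_react * np.asarray(M, dtype=float) + params.k_deg
    return alpha, np.broadcast_to(np.asarray(beta, dtype=float), alpha.shape).copy()


def ti_alpha_beta(
    arch: TranslInhibArch,
    params: TIParams,
    upstream_fine: Mapping[str, np.ndarray],
    k_degP: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble alpha(t) = k_transl*G(t)/(1+REP(t)), beta(t) = k_degP."""
    rep = 0.0
    for mid in arch.mirnas:
        rep = rep + hill_impact(upstream_fine[mid], params.hill[mid])
    G = upstream_fine[arch.gene]
    alpha = params.k_transl * G / (1.0 + rep)
    return alpha, np.full_like(alpha, k_degP)


def predict_downstream(
    arch: TranscrDegrArch | TranslInhibArch,
    params: TDParams | TIParams,
    input_profiles: Mapping[str, Profile | Sequence[float]],
    grid: TimeGrid | None = None,
    initial_value: float = 0.0,
    substeps: int = SUBSTEPS,
    condition=None,
) -> np.ndarray:
    """Integrate the architecture's equation over [0, 6] days.

    ``input_profiles`` must supply every upstream molecule of ``arch`` on the
    grid (for TD: miRNAs and regulator proteins; for TI: miRNAs and the mRNA
    gene).  Returns the 19 predicted downstream values; the value at t=0 is
    ``initial_value`` and all values are nonnegative.
    """
    grid = grid or TimeGrid()
    if isinstance(arch, TranscrDegrArch):
        needed = list(arch.mirnas) + list(arch.regulator_proteins)
    else:
        needed = list(arch.mirnas) + [arch.gene]
    fine: dict[str, np.ndarray] = {}
    for mid in needed:
        if mid not in input_profiles:
            raise DependencyError(f"no upstream profile for molecule {mid!r}")
        prof = input_profiles[mid]
        vals = prof.array if isinstance(prof, Profile) else np.asarray(prof, dtype=float)
        fine[mid] = _upstream_fine(vals, grid, substeps)

    if isinstance(arch, TranscrDegrArch):
        alpha, beta = td_alpha_beta(arch, params, fine)
    else:
        kd = params.decay_for(condition) if condition is not None else params.k_degP
        alpha, beta = ti_alpha_beta(arch, params, fine, kd)

    dt_half = (grid.points[1] - grid.points[0]) / (2.0 * substeps)
    return integrate_linear_rk4(alpha, beta, initial_value, dt_half, substeps)
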
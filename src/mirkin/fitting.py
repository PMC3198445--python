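"""Parameter estimation for the kinetic models.

The estimator follows a dedicated two-layer scheme rather than generic
nonlinear optimization (gradient descent and genetic algorithms are both
slow and initialization-sensitive on these 38-equation systems):

1. The Hill parameters of each regulator are searched on a grid.  Because
   each saturating factor a/(1+a) lies in (0, 1), the search runs over
   factor values at a key instant (the time of the regulator's maximum
   observed wild-type level) and binding-site counts c = 1..c_max; each
   (factor, c) choice is inverted to an affinity gamma.
2. With the Hill parameters fixed, the discretized equations are *linear*
   in the remaining rate constants, which are recovered by nonnegative
   least squares (or an L1 linear program) over the pooled WT+KO residuals.

Every candidate is then scored by integrating the full equation and
measuring the global error of prediction per condition; the candidate
minimizing the worst-condition ErrPred wins, with parsimony tie-breaks.
The search is multi-scale: a coarse factor grid followed by one refinement
pass around the incumbent.  The algorithm is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import linprog, nnls

from .architectures import TranscrDegrArch, TranslInhibArch
from .config import CampaignConfig
from .errors import (
    BudgetError,
    ClampError,
    DegenerateProfileError,
    DependencyError,
    InversionError,
)
from .kinetics import (
    HillParams,
    TDParams,
    TIParams,
    _fine_times,
    integrate_linear_rk4,
    td_alpha_beta,
    ti_alpha_beta,
)
from .profiles import Condition, Profile, TimeGrid
from .validation import FitResult, errpred_global, validate_network

__all__ = [
    "GridSpec",
    "ResidualSystem",
    "discretize_residuals",
    "hill_from_factor",
    "solve_rates",
    "fit_architecture",
    "estimate_decay_rate",
]

from .profiles import Kind, ProfileKey

#: all profiles of a campaign, keyed (molecule_id, kind, condition)
ProfileSet = Mapping[ProfileKey, Profile]


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the Hill-parameter layer."""

    factor_grid: tuple[float, ...] = tuple(round(0.1 * i, 2) for i in range(1, 10))
    c_values: tuple[int, ...] = (1, 2, 3, 4)
    refinement_levels: int = 1
    refine_halfwidth: float = 0.05
    refine_step: float = 0.01

    def __post_init__(self):
        if not all(0.0 < f < 1.0 for f in self.factor_grid):
            raise ValueError("factor grid must lie strictly inside (0, 1)")
        if list(self.factor_grid) != sorted(self.factor_grid):
            raise ValueError("factor grid must be sorted")

    @classmethod
    def from_config(cls, config: CampaignConfig) -> "GridSpec":
        return cls(
            factor_grid=tuple(config.factor_grid),
            c_values=tuple(range(1, config.c_max + 1)),
            refinement_levels=config.refinement_levels,
            refine_halfwidth=config.refine_halfwidth,
            refine_step=config.refine_step,
        )


@dataclass(frozen=True)
class ResidualSystem:
    """Discretized-equation residuals (one per condition/grid interval)."""

    residuals: tuple[float, ...]
    n_unknowns: int


# ---------------------------------------------------------------------------
# data assembly


def _upstream_ids(arch) -> list[tuple[str, Kind]]:
    if isinstance(arch, TranscrDegrArch):
        return [(m, Kind.MIRNA) for m in arch.mirnas] + [
            (p, Kind.PROTEIN) for p in arch.regulator_proteins
        ]
    return [(m, Kind.MIRNA) for m in arch.mirnas] + [(arch.gene, Kind.MRNA)]


def _downstream_kind(arch) -> Kind:
    return Kind.MRNA if isinstance(arch, TranscrDegrArch) else Kind.PROTEIN


def _values(data: ProfileSet, mid: str, kind: Kind, cond: Condition) -> np.ndarray:
    """Grid values of one molecule; a molecule absent under KO is the
    knocked-out one and contributes level 0."""
    if (mid, kind, cond) in data:
        return data[(mid, kind, cond)].array
    if cond is Condition.KO:
        return np.zeros(19)
    raise DependencyError(f"no profile for {kind.value} {mid!r} under {cond.value}")


@dataclass
class _CondData:
    condition: Condition
    downstream: np.ndarray          # observed, 19 grid points
    upstream: dict[str, np.ndarray]  # grid values
    upstream_fine: dict[str, np.ndarray]  # half-substep resolution

    @property
    def mean_obs(self) -> float:
        return float(np.mean(self.downstream))


def _assemble(
    arch, data: ProfileSet, grid: TimeGrid, substeps: int, require_nonzero: bool = True
) -> list[_CondData]:
    """Per-condition observed data for one architecture; conditions whose
    downstream profile is absent or identically zero are not scored (the
    knocked-out protein's own profile under KO)."""
    fine_t = _fine_times(grid, substeps)
    out = []
    for cond in (Condition.WT, Condition.KO):
        key = (arch.downstream_id, _downstream_kind(arch), cond)
        if key not in data:
            continue
        downstream = data[key].array
        if require_nonzero and np.mean(downstream) <= 0:
            continue
        upstream = {mid: _values(data, mid, kind, cond) for mid, kind in _upstream_ids(arch)}
        upstream_fine = {
            mid: np.maximum(PchipInterpolator(grid.array, vals)(fine_t), 0.0)
            for mid, vals in upstream.items()
        }
        out.append(_CondData(cond, downstream, upstream, upstream_fine))
    if not out:
        raise DegenerateProfileError(
            f"downstream {arch.downstream_id!r} has no nonzero profile in any condition"
        )
    return out


# ---------------------------------------------------------------------------
# discretization and linear-rate recovery


def _td_design(arch: TranscrDegrArch, hill: Mapping[str, HillParams], cd: _CondData):
    """Design matrix and target for the TD equation, linear in the rates.

    Row i (interval [t_i, t_i+1]): dG_i = k_transcr*F_i - k_react*G_i*M_i
    - k_deg*G_i with observed levels at t_i.
    """
    rep = np.zeros(19)
    for pid in arch.rep_proteins:
        hp = hill[pid]
        rep += (hp.gamma * cd.upstream[pid]) ** hp.c
    act = np.zeros(19)
    for pid in arch.act_proteins:
        hp = hill[pid]
        act += (hp.gamma * cd.upstream[pid]) ** hp.c
    if arch.act_proteins:
        F = act / ((1.0 + act) * (1.0 + rep))
    else:
        F = 1.0 / (1.0 + rep)
    M = np.zeros(19)
    for mid in arch.mirnas:
        M += cd.upstream[mid]
    G = cd.downstream
    dt = 1.0 / 3.0
    dG = np.diff(G) / dt
    A = np.column_stack([F[:-1], -(G * M)[:-1], -G[:-1]])
    return A, dG


def _ti_design(arch: TranslInhibArch, hill: Mapping[str, HillParams], cd: _CondData, k_degP: float):
    """Design column and target for the TI equation, linear in k_transl."""
    rep = np.zeros(19)
    for mid in arch.mirnas:
        hp = hill[mid]
        rep += (hp.gamma * cd.upstream[mid]) ** hp.c
    G = cd.upstream[arch.gene]
    P = cd.downstream
    dt = 1.0 / 3.0
    dP = np.diff(P) / dt
    A = (G / (1.0 + rep))[:-1].reshape(-1, 1)
    b = dP + k_degP * P[:-1]
    return A, b


def discretize_residuals(
    arch,
    params: TDParams | TIParams,
    data: ProfileSet,
    grid: TimeGrid | None = None,
) -> ResidualSystem:
    """Residuals of the discretized equation at given parameters.

    For each scored condition: 18 interval residuals
    (D(t_{i+1}) - D(t_i))/dt - rhs(t_i), plus the initial-condition residual
    (zero, since prediction starts at the observed value).  Two conditions on
    the 19-point grid give the 38-equation system.
    """
    grid = grid or TimeGrid()
    res: list[float] = []
    for cd in _assemble(arch, data, grid, substeps=1):
        if isinstance(arch, TranscrDegrArch):
            A, b = _td_design(arch, params.hill, cd)
            rates = np.array([params.k_transcr, params.k_react, params.k_deg])
        else:
            A, b = _ti_design(arch, params.hill, cd, params.decay_for(cd.condition))
            rates = np.array([params.k_transl])
        res.extend((b - A @ rates).tolist())
        res.append(0.0)  # initial condition: prediction anchored at D(0)
    return ResidualSystem(residuals=tuple(res), n_unknowns=params.n_params)


def hill_from_factor(factor: float, level: float, c: int) -> float:
    """Invert a saturating factor a/(1+a) with a = (gamma*level)^c to gamma."""
    if not 0.0 < factor < 1.0:
        raise ValueError("factor must lie strictly inside (0, 1)")
    if level <= 0:
        raise InversionError(
            "regulator level is zero at the key instant; its affinity cannot be calibrated"
        )
    a = factor / (1.0 - factor)
    return a ** (1.0 / c) / level


def _solve_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    sol, _ = nnls(A, b)
    return sol


def _solve_l1(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimize sum |A k - b| over k >= 0 via an LP with auxiliary bounds."""
    n, m = A.shape
    c = np.concatenate([np.zeros(m), np.ones(n)])
    A_ub = np.block([[A, -np.eye(n)], [-A, -np.eye(n)]])
    b_ub = np.concatenate([b, -b])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(0, None)] * (m + n), method="highs")
    if not res.success:
        raise RuntimeError(f"L1 rate LP failed: {res.message}")
    return res.x[:m]


def solve_rates(
    arch,
    hill: Mapping[str, HillParams],
    data: ProfileSet,
    grid: TimeGrid | None = None,
    solver: str = "nnls",
    k_degP: Mapping[Condition, float] | None = None,
) -> np.ndarray:
    """Recover the rate constants with the Hill layer fixed.

    Pooled over the scored conditions the discretized residuals are linear
    in the rates; returns the nonnegative minimizer — (k_transcr, k_react,
    k_deg) for TD, (k_transl,) for TI.  An all-zero regressor column simply
    yields a zero rate.
    """
    grid = grid or TimeGrid()
    blocks = []
    targets = []
    for cd in _assemble(arch, data, grid, substeps=1, require_nonzero=False):
        if isinstance(arch, TranscrDegrArch):
            A, b = _td_design(arch, hill, cd)
        else:
            kd = (k_degP or {}).get(cd.condition, 0.0)
            A, b = _ti_design(arch, hill, cd, kd)
        blocks.append(A)
        targets.append(b)
    A = np.vstack(blocks)
    b = np.concatenate(targets)
    if solver == "l1_lp":
        return _solve_l1(A, b)
    return _solve_nnls(A, b)


# ---------------------------------------------------------------------------
# decay-rate pre-estimation


def estimate_decay_rate(
    values: Sequence[float], grid: TimeGrid | None = None, tail_points: int = 7
) -> float:
    """First-order decay rate (1/day) from a profile's declining segment.

    Log-linear least squares over the late part of the segment running from
    the profile maximum to the end (the last ``tail_points`` grid points of
    it, about two days).  Early in the decline synthesis still offsets
    decay and the log-slope underestimates it; the decay rate is identified
    asymptotically, once synthesis is depleted.  Nonnegative by
    construction; 0 for non-declining profiles.
    """
    grid = grid or TimeGrid()
    v = np.asarray(values, dtype=float)
    t = grid.array
    start = int(np.argmax(v))
    seg_t, seg_v = t[start:], v[start:]
    if len(seg_v) > tail_points:
        seg_t, seg_v = seg_t[-tail_points:], seg_v[-tail_points:]
    keep = seg_v > 0
    if keep.sum() < 2:
        return 0.0
    slope = np.polyfit(seg_t[keep], np.log(seg_v[keep]), 1)[0]
    return float(max(-slope, 0.0))


# ---------------------------------------------------------------------------
# the fitter


def _regulators(arch) -> list[str]:
    if isinstance(arch, TranscrDegrArch):
        return sorted(arch.regulator_proteins)
    return sorted(arch.mirnas)


def _key_levels(arch, conds: list[_CondData]) -> dict[str, float]:
    """Calibration level per regulator: its maximum observed WT level."""
    wt = next((cd for cd in conds if cd.condition is Condition.WT), conds[0])
    return {reg: float(np.max(wt.upstream[reg])) for reg in _regulators(arch)}


@dataclass(frozen=True)
class _Candidate:
    objective: float
    errpred: dict
    params: object
    c_total: int
    gammas: tuple[float, ...]

    def better_than(self, other: "_Candidate | None") -> bool:
        if other is None:
            return True
        if self.objective != other.objective:
            return self.objective < other.objective
        if self.c_total != other.c_total:
            return self.c_total < other.c_total
        return self.gammas < other.gammas


def _make_params(arch, hill, rates, k_degP):
    if isinstance(arch, TranscrDegrArch):
        return TDParams(hill=hill, k_transcr=rates[0], k_react=rates[1], k_deg=rates[2])
    kd_wt = k_degP.get(Condition.WT, 0.0)
    kd_ko = k_degP.get(Condition.KO)
    return TIParams(
        hill=hill,
        k_transl=rates[0],
        k_degP=kd_wt,
        k_degP_ko=None if kd_ko is None or kd_ko == kd_wt else kd_ko,
    )


def fit_architecture(
    arch: TranscrDegrArch | TranslInhibArch,
    data: ProfileSet,
    grid_spec: GridSpec | None = None,
    config: CampaignConfig | None = None,
    audit: list | None = None,
) -> FitResult:
    """Fit one architecture's kinetic parameters to both conditions.

    Multi-scale search over (binding sites, saturating factor) per regulator
    with nonnegative-least-squares rate recovery per candidate; each
    candidate is scored by full integration and the worst-condition global
    ErrPred; ties prefer fewer binding sites, then smaller affinities.
    Deterministic for fixed inputs and configuration.
    """
    config = config or CampaignConfig()
    grid_spec = grid_spec or GridSpec.from_config(config)
    grid = TimeGrid()
    conds = _assemble(arch, data, grid, config.substeps)
    regs = _regulators(arch)
    keys = _key_levels(arch, conds)

    k_degP: dict[Condition, float] = {}
    if isinstance(arch, TranslInhibArch):
        wt = next(cd for cd in conds if cd.condition is Condition.WT)
        kd_wt = estimate_decay_rate(wt.downstream, grid)
        for cd in conds:
            if config.condition_specific_kdegp:
                k_degP[cd.condition] = estimate_decay_rate(cd.downstream, grid)
            else:
                k_degP[cd.condition] = kd_wt

    dt_half = (1.0 / 3.0) / (2.0 * config.substeps)

    def evaluate(assignment: dict[str, tuple[int, float]]) -> _Candidate:
        hill = {
            reg: HillParams(c=c, gamma=hill_from_factor(f, keys[reg], c))
            for reg, (c, f) in assignment.items()
        }
        rates = solve_rates(arch, hill, data, grid, config.rate_solver, k_degP)
        params = _make_params(arch, hill, rates, k_degP)
        errpred = {}
        try:
            for cd in conds:
                if isinstance(arch, TranscrDegrArch):
                    alpha, beta = td_alpha_beta(arch, params, cd.upstream_fine)
                else:
                    alpha, beta = ti_alpha_beta(
                        arch, params, cd.upstream_fine, params.decay_for(cd.condition)
                    )
                pred = integrate_linear_rk4(
                    alpha, beta, cd.downstream[0], dt_half, config.substeps
                )
                errpred[cd.condition] = errpred_global(
                    pred, cd.downstream, config.errpred_aggregation
                )
            objective = max(errpred.values())
        except ClampError:
            objective = float("inf")
        cand = _Candidate(
            objective=objective,
            errpred=errpred,
            params=params,
            c_total=sum(c for c, _ in assignment.values()),
            gammas=tuple(hill[reg].gamma for reg in regs),
        )
        if audit is not None:
            audit.append({"assignment": dict(assignment), "objective": objective})
        return cand

    def search(options: dict[str, list[tuple[int, float]]], start: dict | None) -> _Candidate:
        """Exhaustive product search when affordable, else deterministic
        coordinate descent from ``start``."""
        n_total = 1
        for opts in options.values():
            n_total *= len(opts)
        exhaustive = n_total <= config.budget
        if config.search == "exhaustive":
            if n_total > config.budget:
                raise BudgetError(
                    f"{n_total} candidates for {len(regs)} regulators exceed budget {config.budget}"
                )
            exhaustive = True
        elif config.search == "coordinate":
            exhaustive = len(regs) <= 1

        if not regs:
            return evaluate({})

        if exhaustive:
            best = None
            best_assign = None
            names = sorted(options)
            for combo in product(*(options[n] for n in names)):
                assign = dict(zip(names, combo))
                cand = evaluate(assign)
                if cand.better_than(best):
                    best, best_assign = cand, assign
            best_assignment[0] = best_assign
            return best

        # coordinate descent
        assignment = dict(start)
        best = evaluate(assignment)
        for _ in range(config.max_sweeps):
            improved = False
            for reg in sorted(options):
                for opt in options[reg]:
                    if assignment[reg] == opt:
                        continue
                    trial = dict(assignment)
                    trial[reg] = opt
                    cand = evaluate(trial)
                    if cand.better_than(best):
                        best, assignment, improved = cand, trial, True
            if not improved:
                break
        best_assignment[0] = assignment
        return best

    best_assignment: list[dict | None] = [None]
    coarse_options = {
        reg: [(c, f) for c in grid_spec.c_values for f in grid_spec.factor_grid] for reg in regs
    }
    mid_f = grid_spec.factor_grid[len(grid_spec.factor_grid) // 2]
    start = {reg: (grid_spec.c_values[0], mid_f) for reg in regs}
    best = search(coarse_options, start)

    for _ in range(grid_spec.refinement_levels):
        if not regs:
            break
        incumbent = best_assignment[0]
        refined = {}
        for reg in regs:
            c, f = incumbent[reg]
            lo = max(f - grid_spec.refine_halfwidth, grid_spec.refine_step / 10)
            hi = min(f + grid_spec.refine_halfwidth, 1 - grid_spec.refine_step / 10)
            fs = np.round(np.arange(lo, hi + 1e-12, grid_spec.refine_step), 10)
            refined[reg] = [(c, float(ff)) for ff in fs if 0 < ff < 1]
        cand = search(refined, incumbent)
        if cand.better_than(best):
            best = cand

    errpred = {cond: float(v) for cond, v in best.errpred.items()}
    return FitResult(
        architecture=arch,
        params=best.params,
        errpred=errpred,
        n_params=best.params.n_params,
        validated=all(e < config.threshold for e in errpred.values()) and bool(errpred),
    )
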
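"""The grid-search + nonnegative-least-squares estimator."""

import numpy as np
import pytest

from mirkin.architectures import TranscrDegrArch, TranslInhibArch
from mirkin.config import CampaignConfig
from mirkin.errors import BudgetError, InversionError
from mirkin.fitting import (
    GridSpec,
    discretize_residuals,
    estimate_decay_rate,
    fit_architecture,
    hill_from_factor,
    solve_rates,
)
from mirkin.kinetics import HillParams, TDParams, TIParams, predict_downstream
from mirkin.profiles import Condition, Kind, TimeGrid
from mirkin.validation import errpred_global

from conftest import make_profile

DT = 1.0 / 3.0


def discrete_consistent_td(grid, rates=(5.0, 2e-3, 0.4), hill_gamma=1.0, d0=10.0):
    """Data exactly satisfying the forward-discretized TD equation, so the
    linear rate layer has a zero-residual solution at the true rates."""
    t = grid.array
    mirna = 400.0 * np.exp(-0.45 * t)
    repressor = 0.4 + 0.8 * np.exp(-0.5 * (t - 2.0) ** 2)
    hill = {"rep": HillParams(c=1, gamma=hill_gamma)}
    F = 1.0 / (1.0 + hill_gamma * repressor)
    kt, kr, kd = rates
    D = [d0]
    for i in range(18):
        D.append(D[-1] + DT * (kt * F[i] - kr * D[-1] * mirna[i] - kd * D[-1]))
    D = np.asarray(D)
    arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("rep",), act_proteins=())
    data = {}
    for cond in (Condition.WT, Condition.KO):
        data[("m", Kind.MIRNA, cond)] = make_profile("m", Kind.MIRNA, cond, mirna)
        data[("rep", Kind.PROTEIN, cond)] = make_profile("rep", Kind.PROTEIN, cond, repressor)
        data[("G", Kind.MRNA, cond)] = make_profile("G", Kind.MRNA, cond, D)
    return arch, hill, rates, data


class TestDiscretizeResiduals:
    def test_two_conditions_give_38_equations(self, grid):
        arch, hill, rates, data = discrete_consistent_td(grid)
        params = TDParams(hill=hill, k_transcr=rates[0], k_react=rates[1], k_deg=rates[2])
        system = discretize_residuals(arch, params, data, grid)
        assert len(system.residuals) == 38
        assert system.n_unknowns == 5

    def test_exactly_generating_params_zero_residuals(self, grid):
        arch, hill, rates, data = discrete_consistent_td(grid)
        params = TDParams(hill=hill, k_transcr=rates[0], k_react=rates[1], k_deg=rates[2])
        system = discretize_residuals(arch, params, data, grid)
        assert np.max(np.abs(system.residuals)) < 1e-10

    def test_zero_rates_constant_data_zero_residuals(self, grid):
        arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("rep",), act_proteins=())
        data = {}
        for cond in (Condition.WT, Condition.KO):
            for mid, kind in (("m", Kind.MIRNA), ("rep", Kind.PROTEIN), ("G", Kind.MRNA)):
                data[(mid, kind, cond)] = make_profile(mid, kind, cond, np.full(19, 2.0))
        params = TDParams(hill={"rep": HillParams(1, 1.0)}, k_transcr=0, k_react=0, k_deg=0)
        system = discretize_residuals(arch, params, data, grid)
        assert np.max(np.abs(system.residuals)) == 0.0


class TestHillFromFactor:
    def test_half_saturation_unit(self):
        assert hill_from_factor(0.5, 1.0, 1) == pytest.approx(1.0)

    def test_derived_inversion(self):
        assert hill_from_factor(0.8, 2.0, 2) == pytest.approx(1.0)

    @pytest.mark.parametrize("factor,level,c", [(0.3, 2.0, 1), (0.7, 0.5, 3), (0.9, 10.0, 4)])
    def test_round_trip(self, factor, level, c):
        gamma = hill_from_factor(factor, level, c)
        a = (gamma * level) ** c
        assert a / (1 + a) == pytest.approx(factor, rel=1e-12)

    def test_zero_level_uninvertible(self):
        with pytest.raises(InversionError):
            hill_from_factor(0.5, 0.0, 1)


class TestSolveRates:
    def test_recovers_true_rates_on_noise_free_data(self, grid):
        arch, hill, rates, data = discrete_consistent_td(grid)
        got = solve_rates(arch, hill, data, grid)
        assert np.allclose(got, rates, rtol=1e-6)

    def test_all_zero_downstream_gives_zero_rates(self, grid):
        arch, hill, _, data = discrete_consistent_td(grid)
        for cond in (Condition.WT, Condition.KO):
            data[("G", Kind.MRNA, cond)] = make_profile("G", Kind.MRNA, cond, np.zeros(19))
        got = solve_rates(arch, hill, data, grid)
        assert np.allclose(got, 0.0)

    def test_matches_brute_force_rate_grid(self, grid):
        """Exhaustive 3-D grid around the truth cannot beat the NNLS optimum."""
        arch, hill, rates, data = discrete_consistent_td(grid)
        got = solve_rates(arch, hill, data, grid)

        def ssr(k):
            params = TDParams(hill=hill, k_transcr=k[0], k_react=k[1], k_deg=k[2])
            r = discretize_residuals(arch, params, data, grid).residuals
            return float(np.sum(np.square(r)))

        best_grid = min(
            ssr((kt, kr, kd))
            for kt in np.linspace(0, 10, 21)
            for kr in np.linspace(0, 4e-3, 21)
            for kd in np.linspace(0, 0.8, 21)
        )
        assert ssr(got) <= best_grid + 1e-12

    def test_l1_solver_agrees_on_exact_data(self, grid):
        arch, hill, rates, data = discrete_consistent_td(grid)
        got = solve_rates(arch, hill, data, grid, solver="l1_lp")
        assert np.allclose(got, rates, rtol=1e-5)


class TestDecayEstimation:
    def test_pure_exponential_recovered(self, grid):
        kd = 0.45
        values = 3.0 * np.exp(-kd * grid.array)
        assert estimate_decay_rate(values, grid) == pytest.approx(kd, rel=1e-9)

    def test_non_declining_profile_gives_zero(self, grid):
        assert estimate_decay_rate(np.linspace(1, 5, 19), grid) == 0.0


class TestFitArchitecture:
    def test_noise_free_recovery_below_one_percent(self, dense_td_fixture):
        arch, params, _, profiles, _ = dense_td_fixture
        fit = fit_architecture(arch, profiles)
        assert fit.worst_errpred < 1.0
        assert fit.validated

    def test_constant_steady_state_fits_exactly(self, grid):
        arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("rep",), act_proteins=())
        data = {}
        for cond in (Condition.WT, Condition.KO):
            for mid, kind, v in (("m", Kind.MIRNA, 100.0), ("rep", Kind.PROTEIN, 1.0), ("G", Kind.MRNA, 50.0)):
                data[(mid, kind, cond)] = make_profile(mid, kind, cond, np.full(19, v))
        fit = fit_architecture(arch, data)
        assert fit.worst_errpred == pytest.approx(0.0, abs=1e-8)

    def test_simplest_architecture_has_five_unknowns(self, grid):
        arch, hill, rates, data = discrete_consistent_td(grid)
        fit = fit_architecture(arch, data)
        assert fit.n_params == 5

    def test_equals_exhaustive_enumeration_one_regulator(self, dense_td_fixture, grid):
        """Dual route: the fitter's optimum on a 1-regulator search must equal
        independent brute-force enumeration of the full candidate product."""
        t = grid.array
        mirna = 900.0 * np.exp(-0.5 * t)
        repressor = 0.3 + 0.9 * np.exp(-0.5 * (t - 3.0) ** 2)
        arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("rep",), act_proteins=())
        truth = TDParams(hill={"rep": HillParams(1, 1.2)}, k_transcr=120.0, k_react=3e-4, k_deg=0.3)
        traj = predict_downstream(arch, truth, {"m": mirna, "rep": repressor}, grid, 250.0, substeps=60)
        data = {}
        for cond in (Condition.WT, Condition.KO):
            data[("m", Kind.MIRNA, cond)] = make_profile("m", Kind.MIRNA, cond, mirna)
            data[("rep", Kind.PROTEIN, cond)] = make_profile("rep", Kind.PROTEIN, cond, repressor)
            data[("G", Kind.MRNA, cond)] = make_profile("G", Kind.MRNA, cond, traj)

        spec = GridSpec(factor_grid=(0.1, 0.3, 0.5, 0.7, 0.9), c_values=(1, 2, 3, 4), refinement_levels=0)
        fit = fit_architecture(arch, data, grid_spec=spec)

        key_level = float(np.max(repressor))
        best = np.inf
        for c in spec.c_values:
            for f in spec.factor_grid:
                gamma = hill_from_factor(f, key_level, c)
                hill = {"rep": HillParams(c=c, gamma=gamma)}
                kt, kr, kd = solve_rates(arch, hill, data, grid)
                params = TDParams(hill=hill, k_transcr=kt, k_react=kr, k_deg=kd)
                errs = []
                for cond in (Condition.WT, Condition.KO):
                    pred = predict_downstream(
                        arch, params, {"m": mirna, "rep": repressor}, grid, traj[0]
                    )
                    errs.append(errpred_global(pred, data[("G", Kind.MRNA, cond)].array))
                best = min(best, max(errs))
        assert fit.worst_errpred == pytest.approx(best, rel=1e-12)

    def test_returned_objective_is_minimum_of_audit(self, dense_td_fixture):
        arch, _, _, profiles, _ = dense_td_fixture
        audit: list = []
        fit = fit_architecture(arch, profiles, audit=audit)
        assert len(audit) > 0
        assert fit.worst_errpred == pytest.approx(min(a["objective"] for a in audit), rel=1e-12)

    def test_enlarging_factor_grid_never_worsens(self, dense_td_fixture):
        arch, _, _, profiles, _ = dense_td_fixture
        small = GridSpec(factor_grid=(0.3, 0.5, 0.7), refinement_levels=0)
        big = GridSpec(factor_grid=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9), refinement_levels=0)
        fit_small = fit_architecture(arch, profiles, grid_spec=small)
        fit_big = fit_architecture(arch, profiles, grid_spec=big)
        assert fit_big.worst_errpred <= fit_small.worst_errpred + 1e-12

    def test_exhaustive_mode_budget_error(self, dense_td_fixture):
        arch, _, _, profiles, _ = dense_td_fixture
        config = CampaignConfig(search="exhaustive", budget=3)
        with pytest.raises(BudgetError):
            fit_architecture(arch, profiles, config=config)
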
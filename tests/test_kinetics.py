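"""Hill impacts, committed fraction, the two equations and their integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import PchipInterpolator

from mirkin.architectures import TranscrDegrArch, TranslInhibArch
from mirkin.errors import DependencyError
from mirkin.kinetics import (
    HillParams,
    TDParams,
    TIParams,
    committed_fraction,
    hill_impact,
    predict_downstream,
    saturating_factor,
    synthetic_impacts,
    transcr_degr_rhs,
    transl_inhib_rhs,
)
from mirkin.profiles import TimeGrid


class TestHillImpact:
    def test_zero_level(self):
        assert hill_impact(0.0, HillParams(c=3, gamma=2.0)) == 0.0

    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_half_saturation(self, c):
        a = hill_impact(1.0, HillParams(c=c, gamma=1.0))
        assert a == 1.0
        assert saturating_factor(a) == 0.5

    def test_direct_arithmetic(self):
        a = hill_impact(2.0, HillParams(c=2, gamma=1.0))
        assert a == 4.0
        assert saturating_factor(a) == pytest.approx(0.8)


class TestSyntheticImpacts:
    def test_empty_sums(self):
        assert synthetic_impacts([], [], [], []) == (0.0, 0.0)

    def test_additivity(self):
        rep, act = synthetic_impacts([1.0, 3.0], [HillParams(1, 1.0)] * 2, [], [])
        assert rep == 4.0 and act == 0.0

    def test_matches_term_by_term_resummation(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(0, 5, 4)
        hps = [HillParams(c=int(c), gamma=g) for c, g in zip(rng.integers(1, 5, 4), rng.uniform(0.1, 2, 4))]
        rep, act = synthetic_impacts(levels[:2], hps[:2], levels[2:], hps[2:])
        expected_rep = sum((hp.gamma * x) ** hp.c for x, hp in zip(levels[:2], hps[:2]))
        expected_act = sum((hp.gamma * x) ** hp.c for x, hp in zip(levels[2:], hps[2:]))
        assert rep == pytest.approx(expected_rep, rel=1e-12)
        assert act == pytest.approx(expected_act, rel=1e-12)


class TestCommittedFraction:
    @pytest.mark.parametrize(
        "rep,act,has_act,expected",
        [(0.0, 0.0, False, 1.0), (1.0, 0.0, False, 0.5), (0.0, 3.0, True, 0.75)],
    )
    def test_values(self, rep, act, has_act, expected):
        assert committed_fraction(rep, act, has_act) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 50), st.floats(0, 50), st.floats(0.01, 10), st.booleans()
    )
    def test_bounded_and_monotone(self, rep, act, delta, has_act):
        f = committed_fraction(rep, act, has_act)
        assert 0.0 <= f <= 1.0
        assert committed_fraction(rep + delta, act, has_act) <= f
        if has_act:
            assert committed_fraction(rep, act + delta, has_act) >= f


class TestRhs:
    def test_all_rates_zero(self):
        p = TDParams(hill={}, k_transcr=0, k_react=0, k_deg=0)
        assert transcr_degr_rhs(1.0, 1.0, 0.5, p) == 0.0

    def test_pure_synthesis_at_extinction(self):
        p = TDParams(hill={}, k_transcr=2.0, k_react=0.5, k_deg=0.5)
        assert transcr_degr_rhs(0.0, 5.0, 1.0, p) == 2.0

    def test_td_direct_arithmetic(self):
        p = TDParams(hill={}, k_transcr=2.0, k_react=0.3, k_deg=0.2)
        assert transcr_degr_rhs(1.0, 1.0, 0.5, p) == pytest.approx(0.5)

    def test_uninhibited_translation(self):
        p = TIParams(hill={}, k_transl=0.7, k_degP=0.3)
        assert transl_inhib_rhs(0.0, 4.0, 0.0, p) == pytest.approx(2.8)

    def test_pure_decay(self):
        p = TIParams(hill={}, k_transl=0.0, k_degP=0.25)
        assert transl_inhib_rhs(2.0, 4.0, 1.0, p) == pytest.approx(-0.5)

    def test_ti_direct_arithmetic(self):
        p = TIParams(hill={}, k_transl=1.0, k_degP=0.25)
        assert transl_inhib_rhs(2.0, 4.0, 1.0, p) == pytest.approx(1.5)


def _td_arch():
    return TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=(), act_proteins=("a",))


class TestPredictDownstream:
    def test_zero_rates_constant(self, grid):
        params = TDParams(hill={"a": HillParams(1, 1.0)}, k_transcr=0, k_react=0, k_deg=0)
        upstream = {"m": np.ones(19), "a": np.ones(19)}
        pred = predict_downstream(_td_arch(), params, upstream, grid, initial_value=5.0)
        assert np.allclose(pred, 5.0)

    def test_half_life_three_days(self, grid):
        # activator level 0 => committed fraction 0; no miRNA present => pure decay
        params = TDParams(
            hill={"a": HillParams(1, 1.0)}, k_transcr=10.0, k_react=0.2, k_deg=np.log(2) / 3
        )
        upstream = {"m": np.zeros(19), "a": np.zeros(19)}
        pred = predict_downstream(_td_arch(), params, upstream, grid, initial_value=8.0)
        assert pred[9] == pytest.approx(4.0, rel=1e-6)  # t = 3 days
        assert pred[18] == pytest.approx(2.0, rel=1e-6)

    def test_closed_form_linear_ode(self, grid):
        # constant committed fraction (constant activator), no miRNA coupling
        params = TDParams(
            hill={"a": HillParams(1, 1.0)}, k_transcr=6.0, k_react=0.0, k_deg=0.5
        )
        upstream = {"m": np.zeros(19), "a": np.ones(19)}
        F = committed_fraction(0.0, 1.0, True)  # 0.25
        g0, t = 2.0, grid.array
        expected = (g0 - params.k_transcr * F / params.k_deg) * np.exp(-params.k_deg * t) + (
            params.k_transcr * F / params.k_deg
        )
        pred = predict_downstream(_td_arch(), params, upstream, grid, initial_value=g0)
        assert np.allclose(pred, expected, rtol=1e-7)

    def test_missing_upstream_named(self, grid):
        params = TDParams(hill={"a": HillParams(1, 1.0)}, k_transcr=1, k_react=0, k_deg=0)
        with pytest.raises(DependencyError, match="a"):
            predict_downstream(_td_arch(), params, {"m": np.ones(19)}, grid, 1.0)

    def test_agrees_with_fine_step_euler(self, grid):
        """Independent oracle: forward Euler at steps h and h/2 with
        Richardson extrapolation (truncation O(h^2)), the Hill algebra
        recomputed from scratch."""
        rng = np.random.default_rng(11)
        t = grid.array
        mirna = rng.uniform(100, 1000) * np.exp(-rng.uniform(0.2, 0.6) * t)
        act = rng.uniform(0.5, 2.0) * np.exp(-rng.uniform(0.1, 0.4) * t)
        rep = 0.3 + rng.uniform(0.2, 1.0) * np.exp(-0.5 * (t - 3) ** 2)
        arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("r",), act_proteins=("a",))
        params = TDParams(
            hill={"r": HillParams(2, 1.1), "a": HillParams(1, 1.4)},
            k_transcr=3.0,
            k_react=1e-3,
            k_deg=0.4,
        )
        upstream = {"m": mirna, "a": act, "r": rep}
        pred = predict_downstream(arch, params, upstream, grid, initial_value=2.0)

        def euler(n_per_interval):
            dt = (1.0 / 3.0) / n_per_interval
            times = np.linspace(0.0, 6.0, 18 * n_per_interval + 1)
            m_f = np.maximum(PchipInterpolator(t, mirna)(times), 0)
            a_f = np.maximum(PchipInterpolator(t, act)(times), 0)
            r_f = np.maximum(PchipInterpolator(t, rep)(times), 0)
            REP = (1.1 * r_f) ** 2
            ACT = (1.4 * a_f) ** 1
            F = ACT / ((1 + ACT) * (1 + REP))
            alpha = (3.0 * F).tolist()
            beta = (1e-3 * m_f + 0.4).tolist()
            y = 2.0
            out = [y]
            for i in range(len(times) - 1):
                y = y + dt * (alpha[i] - beta[i] * y)
                if (i + 1) % n_per_interval == 0:
                    out.append(y)
            return np.asarray(out)

        coarse, fine = euler(20_000), euler(40_000)
        oracle = 2.0 * fine - coarse  # Richardson: cancels the O(h) error
        assert np.allclose(pred, oracle, rtol=1e-6)


class TestModelInvariances:
    def test_scale_invariance_machine_precision(self, dense_td_fixture, grid):
        arch, params, upstream, _, truth = dense_td_fixture
        s = 137.0
        scaled_upstream = {k: s * np.asarray(v) for k, v in upstream.items()}
        scaled_params = TDParams(
            hill={k: HillParams(hp.c, hp.gamma / s) for k, hp in params.hill.items()},
            k_transcr=params.k_transcr,
            k_react=params.k_react / s,
            k_deg=params.k_deg,
        )
        pred = predict_downstream(arch, params, upstream, grid, 300.0)
        pred_scaled = predict_downstream(arch, scaled_params, scaled_upstream, grid, 300.0)
        assert np.allclose(pred, pred_scaled, rtol=1e-12, atol=1e-12)

    def test_monotone_repression(self, grid):
        arch = TranscrDegrArch(gene="G", mirnas=("m",), rep_proteins=("r",), act_proteins=())
        params = TDParams(hill={"r": HillParams(1, 1.0)}, k_transcr=5.0, k_react=1e-3, k_deg=0.3)
        t = grid.array
        base = {"m": 200 * np.exp(-0.3 * t), "r": 0.5 + 0.1 * t}
        raised = {"m": base["m"], "r": base["r"] + 0.8}
        pred_base = predict_downstream(arch, params, base, grid, 10.0)
        pred_up = predict_downstream(arch, params, raised, grid, 10.0)
        assert np.all(pred_up <= pred_base + 1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        st.floats(0, 5), st.floats(0, 2e-3), st.floats(0, 2), st.floats(0, 20)
    )
    def test_nonnegativity(self, k_transcr, k_react, k_deg, g0):
        arch = _td_arch()
        params = TDParams(
            hill={"a": HillParams(1, 1.0)}, k_transcr=k_transcr, k_react=k_react, k_deg=k_deg
        )
        grid = TimeGrid()
        t = grid.array
        upstream = {"m": 300 * np.exp(-0.4 * t), "a": np.exp(-0.2 * t)}
        pred = predict_downstream(arch, params, upstream, grid, initial_value=g0)
        assert np.all(pred >= 0)
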
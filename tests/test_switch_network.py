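"""Unit and property tests for the miR-451/AMPK switch."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glioswitch.switch_network import (
    SwitchParams,
    SwitchState,
    ampk_nullcline,
    continue_branch,
    glucose_deprivation_response,
    integrate_switch,
    steady_states,
    switch_jacobian,
    switch_rhs,
)


def _nullcline_intersection_oracle(G, p, n_grid=200_000):
    """Count equilibria by intersecting the two nullclines.

    Independent route: the A-nullcline gives A1(M) explicitly; the
    M-nullcline is solved for A as A2(M) = sqrt((k1*k2^2/(M-G) - k2^2)/alpha)
    wherever M > G; equilibria are sign changes of A1 - A2.
    """
    M = np.linspace(G + 1e-9, G + p.k1 - 1e-9, n_grid)
    A1 = ampk_nullcline(M, p)
    inner = (p.k1 * p.k2**2 / (M - G) - p.k2**2) / max(p.alpha, 1e-300)
    valid = inner >= 0
    A2 = np.sqrt(np.where(valid, inner, np.nan))
    d = A1 - A2
    sign = np.sign(d)
    ok = np.isfinite(d[:-1]) & np.isfinite(d[1:])
    count = int(np.sum((sign[:-1] * sign[1:] < 0) & ok))
    count += int(np.sum(d == 0))
    return count


class TestRhs:
    def test_origin_is_equilibrium_without_inputs(self):
        p = SwitchParams(S=0.0, k1=0.0, k3=0.0)
        dM, dA = switch_rhs(0.0, 0.0, 0.0, p)
        assert dM == 0.0 and dA == 0.0

    def test_production_bound_forces_decay(self, params):
        # beyond the production bound the linear decay must dominate
        for M in (params.k1 + 0.5 + 0.1, params.k1 + 10.0):
            dM, _ = switch_rhs(M, 0.3, 0.5, params)
            assert dM < 0
        _, dA = switch_rhs(0.5, params.S + params.k3 + 1e-6, 0.5, params)
        assert dA < 0

    def test_rhs_vanishes_on_computed_equilibria(self, params):
        for eq in steady_states(0.5, params):
            dM, dA = switch_rhs(eq.M, eq.A, 0.5, params)
            assert abs(dM) < 1e-10 and abs(dA) < 1e-10

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            switch_rhs(-0.1, 0.0, 0.5, params)
        with pytest.raises(ValueError):
            switch_rhs(0.1, 0.0, -0.5, params)
        with pytest.raises(ValueError):
            SwitchParams(k1=-1.0)
        with pytest.raises(ValueError):
            SwitchParams(eps=0.0)

    def test_jacobian_matches_finite_differences(self, params):
        M, A, G, h = 1.3, 0.8, 0.5, 1e-6
        J = switch_jacobian(M, A, params)
        num = np.empty((2, 2))
        for j, (dM_, dA_) in enumerate(((h, 0.0), (0.0, h))):
            up = switch_rhs(M + dM_, A + dA_, G, params)
            dn = switch_rhs(M - dM_, A - dA_, G, params)
            num[0, j] = (up[0] - dn[0]) / (2 * h)
            num[1, j] = (up[1] - dn[1]) / (2 * h)
        assert np.allclose(J, num, rtol=1e-5, atol=1e-5)


class TestSteadyStates:
    def test_bistable_at_intermediate_glucose(self, params):
        eqs = steady_states(0.5, params)
        assert len(eqs) == 3
        assert [e.stability for e in eqs] == ["stable", "unstable", "stable"]

    def test_all_production_off_leaves_origin(self):
        p = SwitchParams(k1=0.0, k3=0.0, S=0.0)
        eqs = steady_states(0.0, p)
        assert len(eqs) == 1
        assert eqs[0].M == pytest.approx(0.0, abs=1e-10)
        assert eqs[0].A == pytest.approx(0.0, abs=1e-10)
        assert eqs[0].stability == "stable"

    def test_monostable_at_high_glucose(self, params):
        eqs = steady_states(0.8, params)
        assert len(eqs) == 1
        assert eqs[0].M > params.M_th  # the surviving branch is the upper one

    def test_equilibria_lie_in_production_box(self, params):
        for G in (0.0, 0.3, 0.5, 0.9):
            for eq in steady_states(G, params):
                assert -1e-12 <= eq.M <= G + params.k1 + 1e-9
                assert -1e-12 <= eq.A <= params.S + params.k3 + 1e-9

    def test_root_count_matches_nullcline_oracle_on_random_params(self, rng):
        """Dense nullcline-intersection scan agrees on 50 random parameter sets."""
        for _ in range(50):
            p = SwitchParams(
                k1=rng.uniform(1.0, 6.0),
                k2=rng.uniform(0.5, 2.0),
                alpha=rng.uniform(0.2, 3.0),
                k3=rng.uniform(1.0, 6.0),
                k4=rng.uniform(0.5, 2.0),
                beta=rng.uniform(0.2, 3.0),
                S=rng.uniform(0.0, 0.5),
            )
            G = rng.uniform(0.0, 1.0)
            found = steady_states(G, p)
            expected = _nullcline_intersection_oracle(G, p)
            assert len(found) == expected, f"params={p}, G={G}"


class TestContinuation:
    def test_fold_locations_near_reference_values(self, params):
        b = continue_branch(params, (0.0, 1.0), 0.005)
        assert b.bistable
        assert b.fold_high == pytest.approx(0.6, abs=0.05)
        assert b.fold_low == pytest.approx(0.4, abs=0.05)

    def test_three_equilibria_strictly_inside_window_one_outside(self, params):
        b = continue_branch(params, (0.0, 1.0), 0.005)
        for G in np.linspace(b.fold_low + 0.01, b.fold_high - 0.01, 7):
            assert len(steady_states(float(G), params)) == 3
        for G in (b.fold_low - 0.02, b.fold_high + 0.02):
            assert len(steady_states(float(G), params)) == 1

    def test_branch_stability_pattern(self, params):
        b = continue_branch(params, (0.0, 1.0), 0.01)
        # wherever three equilibria coexist the middle one is unstable
        for G in np.unique(b.G):
            sel = np.isclose(b.G, G)
            if sel.sum() == 3:
                stab = b.stability[sel][np.argsort(b.M[sel])]
                assert list(stab) == ["stable", "unstable", "stable"]

    def test_no_inhibition_gives_monotone_branch(self):
        p = SwitchParams(alpha=0.0, beta=0.0)
        b = continue_branch(p, (0.0, 1.0), 0.01)
        assert not b.bistable
        assert b.fold_low is None and b.fold_high is None
        # one equilibrium per G, M increasing with G
        assert b.G.size == np.unique(b.G).size
        assert np.all(np.diff(b.M) > 0)

    def test_folds_agree_with_brute_force_root_count_scan(self, params):
        b = continue_branch(params, (0.0, 1.0), 0.01, fold_tol=1e-4)
        for fold in (b.fold_low, b.fold_high):
            Gs = np.arange(fold - 5e-4, fold + 5e-4, 1e-4)
            counts = np.array([len(steady_states(float(G), params)) for G in Gs])
            changes = np.nonzero(np.diff(counts))[0]
            assert changes.size >= 1
            nearest = Gs[changes[np.argmin(np.abs(Gs[changes] - fold))]]
            assert abs(nearest - fold) <= 2e-4


class TestIntegration:
    def test_fixed_point_stays_fixed(self, params):
        eq = steady_states(0.8, params)[0]
        sol = integrate_switch(SwitchState(eq.M, eq.A), 0.8, params, (0.0, 100.0),
                               t_eval=np.linspace(0, 100, 201))
        assert np.max(np.abs(sol.y[0] - eq.M)) < 1e-6
        assert np.max(np.abs(sol.y[1] - eq.A)) < 1e-6

    def test_middle_equilibrium_separates_basins(self, params):
        low, mid, high = steady_states(0.5, params)
        for delta, target in ((+0.01, high), (-0.01, low)):
            sol = integrate_switch(SwitchState(mid.M + delta, mid.A), 0.5, params,
                                   (0.0, 300.0))
            assert sol.y[0, -1] == pytest.approx(target.M, abs=1e-4)
            assert sol.y[1, -1] == pytest.approx(target.A, abs=1e-4)

    def test_hysteresis_loop_under_slow_triangular_sweep(self, params):
        T = 4000.0

        def ramp(t):
            return 2 * t / T if t < T / 2 else 2 * (T - t) / T

        low = min(steady_states(0.0, params), key=lambda e: e.M)
        t_eval = np.linspace(0.0, T, 8001)
        sol = integrate_switch(SwitchState(low.M, low.A), ramp, params, (0.0, T),
                               t_eval=t_eval, rtol=1e-9, atol=1e-11)
        G = np.array([ramp(t) for t in sol.t])
        M = sol.y[0]
        up = sol.t < T / 2
        # switch commits to the upper branch only past the upper fold,
        # and returns only below the lower fold
        G_jump_up = G[up][np.argmax(M[up] > params.M_th)]
        down_idx = np.nonzero((~up) & (M < params.M_th))[0][0]
        G_jump_down = G[down_idx]
        assert G_jump_up > G_jump_down
        assert G_jump_up == pytest.approx(0.6, abs=0.07)
        assert G_jump_down == pytest.approx(0.4, abs=0.07)
        area = -np.trapezoid(M, G)  # closed loop traversed counterclockwise
        assert area > 0.1

    def test_positivity_and_boundedness_on_random_trajectories(self, rng):
        """Nonnegative initial data stays nonnegative and within production bounds."""
        for _ in range(100):
            p = SwitchParams(
                k1=rng.uniform(0.5, 6.0), alpha=rng.uniform(0.1, 3.0),
                k3=rng.uniform(0.5, 6.0), beta=rng.uniform(0.1, 3.0),
                S=rng.uniform(0.0, 0.5), eps=rng.uniform(0.01, 0.2),
            )
            G = rng.uniform(0.0, 1.5)
            y0 = SwitchState(rng.uniform(0.0, p.k1 + 2), rng.uniform(0.0, p.k3 + 2))
            sol = integrate_switch(y0, G, p, (0.0, 30.0), rtol=1e-8, atol=1e-10)
            assert sol.y.min() > -1e-8
            assert sol.y[0, -1] <= G + p.k1 + 1e-6
            assert sol.y[1, -1] <= p.S + p.k3 + 1e-6

    def test_slow_fast_limit_approaches_quasi_static_M(self, params):
        """As eps shrinks, M hugs its nullcline and A follows the reduced flow."""
        G = 0.5

        def m_qss(A, p):
            return G + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * A**2)

        A0 = 3.0
        t_eval = np.linspace(0.0, 8.0, 161)
        red = solve_ivp(
            lambda t, y: [params.S + params.k3 * params.k4**2
                          / (params.k4**2 + params.beta * m_qss(y[0], params) ** 2) - y[0]],
            (0.0, 8.0), [A0], rtol=1e-10, atol=1e-12, t_eval=t_eval, dense_output=False)
        errors = []
        for eps in (0.02, 0.002, 0.0002):
            p = SwitchParams(eps=eps)
            sol = integrate_switch(SwitchState(m_qss(A0, p), A0), G, p, (0.0, 8.0),
                                   t_eval=t_eval, rtol=1e-10, atol=1e-12)
            err = np.max(np.abs(sol.y[1] - red.y[0])) + np.max(
                np.abs(sol.y[0] - m_qss(sol.y[1], p)))
            errors.append(err)
        assert errors[0] > errors[1] > errors[2]


class TestDeprivation:
    def test_identical_levels_give_zero_reduction(self, params):
        assert glucose_deprivation_response(params, G_high=0.7, G_low=0.7) == 0.0
        with pytest.raises(ValueError):
            glucose_deprivation_response(params, G_high=0.3, G_low=0.7)

    def test_reduction_exceeds_80_percent_with_default_mapping(self, params):
        assert glucose_deprivation_response(params) > 80.0

    def test_matches_relaxation_oracle(self, params):
        """Branch-snapped result equals a raw long-time relaxation computation."""
        G_high, G_low = 0.7, 0.7 * 0.3 / 4.5
        top = max(steady_states(G_high, params), key=lambda e: e.M)
        sol = integrate_switch(SwitchState(top.M, top.A), G_low, params, (0.0, 600.0),
                               rtol=1e-11, atol=1e-13)
        oracle = 100.0 * (1.0 - sol.y[0, -1] / top.M)
        assert glucose_deprivation_response(params, G_high, G_low) == pytest.approx(
            oracle, abs=0.1)
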
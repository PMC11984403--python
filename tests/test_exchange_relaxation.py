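"""Forward-model checks against independent brute-force oracles.

The closed-form biexponential/steady-state solutions are compared with
dense eigendecomposition, matrix-exponential and explicit pulse-train
simulations that never share code with the implementation paths.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import wexdce as w
from wexdce.exchange_relaxation import exchange_matrix_2site, exchange_matrix_3site

from conftest import random_three_site, random_two_site


class TestApparentBiexponential:
    def test_no_exchange_limit_decouples_pools(self):
        sol = w.apparent_biexponential(
            w.TwoSiteParams(p_i=0.6, k_io=0.0, R1_i=0.5, R1_o=5.0)
        )
        assert sol.R1_L == pytest.approx(0.5, abs=1e-12)
        assert sol.R1_S == pytest.approx(5.0, abs=1e-12)
        assert sol.a_L == pytest.approx(0.6, abs=1e-12)
        assert sol.a_S == pytest.approx(0.4, abs=1e-12)

    def test_fast_exchange_limit_population_mean(self):
        sol = w.apparent_biexponential(
            w.TwoSiteParams(p_i=0.5, k_io=1e5, R1_i=0.4, R1_o=2.4)
        )
        assert sol.R1_L == pytest.approx(1.4, rel=1e-4)
        assert sol.a_L == pytest.approx(1.0, abs=1e-6)

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(25):
            params = random_two_site(rng)
            sol = w.apparent_biexponential(params)
            a_mat = exchange_matrix_2site(params)
            eigvals, eigvecs = np.linalg.eig(a_mat)
            order = np.argsort(eigvals)
            lam = np.sort(eigvals.real)
            assert sol.R1_L == pytest.approx(lam[0], rel=1e-10)
            assert sol.R1_S == pytest.approx(lam[1], rel=1e-10)
            # apparent fractions from expanding p on the eigenbasis
            coeff = np.linalg.solve(eigvecs, np.array([params.p_i, params.p_o]))
            fracs = coeff * eigvecs.sum(axis=0)
            assert sol.a_L == pytest.approx(fracs[order[0]].real, rel=1e-9, abs=1e-12)

    def test_fractions_sum_to_one_and_slow_rate_below_mean(self, rng):
        for _ in range(50):
            params = random_two_site(rng)
            sol = w.apparent_biexponential(params)
            assert sol.a_L + sol.a_S == pytest.approx(1.0, abs=1e-12)
            # slow apparent rate is bracketed by the no-exchange (min pool
            # rate) and fast-exchange (population mean) limits
            mean_rate = params.p_i * params.R1_i + params.p_o * params.R1_o
            assert min(params.R1_i, params.R1_o) - 1e-9 <= sol.R1_L <= mean_rate + 1e-9

    def test_slow_rate_monotone_in_k_io(self):
        rates = [
            w.apparent_biexponential(
                w.TwoSiteParams(p_i=0.7, k_io=k, R1_i=0.4, R1_o=3.0)
            ).R1_L
            for k in np.linspace(0.0, 30.0, 40)
        ]
        assert np.all(np.diff(rates) > 0)

    def test_p_o_degenerate_rejected(self):
        with pytest.raises(ValueError):
            w.TwoSiteParams(p_i=1.0, k_io=1.0, R1_i=0.5, R1_o=1.0)


class TestIrTseSignal:
    params = w.TwoSiteParams(p_i=0.7, k_io=5.0, R1_i=0.4, R1_o=3.5)

    def test_perfect_inversion_at_zero_delay(self):
        assert w.ir_tse_signal(np.array([0.0]), self.params)[0] == pytest.approx(-1.0)

    def test_full_recovery_at_long_delay(self):
        sol = w.apparent_biexponential(self.params)
        sig = w.ir_tse_signal(np.array([10.0 / sol.R1_L]), self.params)
        assert sig[0] == pytest.approx(1.0, abs=1e-4)

    def test_monotone_recovery_for_ideal_inversion(self):
        t = np.linspace(0.0, 10.0, 200)
        sig = w.ir_tse_signal(t, self.params, inv_eff=1.0)
        assert np.all(np.diff(sig) >= 0)

    def test_matches_matrix_exponential_propagation(self):
        """Closed form vs Bloch-McConnell ODE from the inverted state."""
        t = 0.5
        a_mat = exchange_matrix_2site(self.params)
        p = np.array([self.params.p_i, self.params.p_o])
        m = p + expm(-a_mat * t) @ (-2.0 * p)  # m(0) = -p after ideal inversion
        expected = m.sum()
        got = w.ir_tse_signal(np.array([t]), self.params)[0]
        assert got == pytest.approx(expected, abs=1e-8)

    def test_closed_form_vs_ode_over_random_draws(self, rng):
        """Eigen-solution/propagator equivalence on many random draws."""
        t = np.linspace(0.0, 5.0, 30)[1:]
        worst = 0.0
        for _ in range(100):
            params = random_two_site(rng)
            a_mat = exchange_matrix_2site(params)
            p = np.array([params.p_i, params.p_o])
            ref = np.array([(p + expm(-a_mat * ti) @ (-2 * p)).sum() for ti in t])
            got = w.ir_tse_signal(t, params)
            worst = max(worst, np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-3)))
        assert worst < 1e-7

    def test_fast_exchange_ir_monoexponential(self):
        params = w.TwoSiteParams(p_i=0.7, k_io=1e5, R1_i=0.4, R1_o=3.0)
        r_mean = 0.7 * 0.4 + 0.3 * 3.0
        t = np.linspace(0.05, 3.0, 50)
        got = w.ir_tse_signal(t, params)
        mono = 1.0 - 2.0 * np.exp(-r_mean * t)
        assert np.max(np.abs(got - mono) / np.maximum(np.abs(mono), 0.1)) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            w.ir_tse_signal(np.array([-0.1]), self.params)
        with pytest.raises(ValueError):
            w.ir_tse_signal(np.array([0.1]), self.params, inv_eff=0.0)


class TestLongitudinalPropagate:
    def test_equilibrium_is_fixed_point(self, rng):
        params = random_three_site(rng)
        p = params.fractions
        m = w.longitudinal_propagate(params, 1.1, 0.9, p, 0.7)
        np.testing.assert_allclose(m, p, atol=1e-12)

    def test_zero_dt_is_identity(self, rng):
        params = random_three_site(rng)
        m0 = np.array([0.1, -0.2, 0.4])
        np.testing.assert_array_equal(
            w.longitudinal_propagate(params, 2.0, 1.5, m0, 0.0), m0
        )

    def test_matches_runge_kutta_oracle(self, rng):
        for _ in range(10):
            params = random_three_site(rng)
            r1_b, r1_o = rng.uniform(0.5, 10.0, 2)
            m0 = rng.uniform(-1.0, 1.0, 3)
            p = params.fractions
            a_mat = exchange_matrix_3site(params, r1_b, r1_o)
            sol = solve_ivp(
                lambda t, m: -a_mat @ (m - p),
                [0.0, 0.1],
                m0,
                rtol=1e-12,
                atol=1e-14,
            )
            got = w.longitudinal_propagate(params, r1_b, r1_o, m0, 0.1)
            np.testing.assert_allclose(got, sol.y[:, -1], atol=1e-9)


def pulse_train_signal(params, r1_b, r1_o, fa, tr, n_pulses=2000):
    """Independent oracle: explicit RF pulse train to convergence."""
    cos_a = np.cos(np.deg2rad(fa))
    m = params.fractions.copy()
    for _ in range(n_pulses):
        m = w.longitudinal_propagate(params, r1_b, r1_o, cos_a * m, tr)
    return np.sin(np.deg2rad(fa)) * m.sum()


class TestSpgrFrameSignal:
    def test_degenerate_pools_collapse_to_single_pool_spgr(self):
        r, fa, tr = 1.2, 15.0, 0.01
        params = w.ThreeSiteParams(
            p_b=0.05, p_o=0.3, p_i=0.65, k_bo=2.0, k_io=5.0,
            R1_b0=r, R1_o0=r, R1_i=r,
        )
        e1 = np.exp(-r * tr)
        fa_r = np.deg2rad(fa)
        expected = np.sin(fa_r) * (1 - e1) / (1 - e1 * np.cos(fa_r))
        assert w.spgr_frame_signal(params, r, r, fa, tr) == pytest.approx(
            expected, rel=1e-12
        )

    def test_signal_vanishes_at_small_flip_angle(self, rng):
        params = random_three_site(rng)
        assert w.spgr_frame_signal(params, 1.0, 1.0, 1e-4, 0.005) < 1e-5

    def test_matches_pulse_train_simulation(self, rng):
        params = w.ThreeSiteParams(
            p_b=0.05, p_o=0.30, p_i=0.65, k_bo=2.0, k_io=5.0,
            R1_b0=2.5, R1_o0=1.8, R1_i=0.55,
        )
        got = w.spgr_frame_signal(params, 2.5, 1.8, 10.0, 0.005)
        ref = pulse_train_signal(params, 2.5, 1.8, 10.0, 0.005)
        assert got == pytest.approx(ref, rel=1e-6)

    def test_matches_pulse_train_random_draws(self, rng):
        for _ in range(5):
            params = random_three_site(rng)
            r1_b, r1_o = rng.uniform(0.5, 20.0, 2)
            got = w.spgr_frame_signal(params, r1_b, r1_o, 12.0, 0.01)
            ref = pulse_train_signal(params, r1_b, r1_o, 12.0, 0.01)
            assert got == pytest.approx(ref, rel=1e-6)

    def test_invalid_flip_angle(self, rng):
        params = random_three_site(rng)
        with pytest.raises(ValueError):
            w.spgr_frame_signal(params, 1.0, 1.0, 95.0, 0.005)
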
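import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.integrate import solve_ivp

from burdendmf.dmf import (
    GAIN_EPS,
    BurdenMap,
    DMFParameters,
    FICWeights,
    GainParameters,
    calibrate_fic,
    compute_gains,
    currents,
    integrate,
    simulate_mean_rates,
    transfer_rate,
)
from burdendmf.connectome import StructuralConnectome


class TestTransferRate:
    def test_singularity_limit_is_inverse_d(self):
        p = DMFParameters()
        I_sing = p.b_E / p.a_E  # aI - b = 0
        assert np.isclose(transfer_rate(I_sing, p.a_E, p.b_E, p.d_E), 1 / p.d_E)
        assert np.isclose(transfer_rate(I_sing, p.a_E, p.b_E, p.d_E), 6.25)

    def test_continuity_at_singularity(self):
        p = DMFParameters()
        I_sing = p.b_E / p.a_E
        eps = 1e-9
        lo = transfer_rate(I_sing - eps, p.a_E, p.b_E, p.d_E)
        hi = transfer_rate(I_sing + eps, p.a_E, p.b_E, p.d_E)
        assert abs(lo - 6.25) < 1e-5 and abs(hi - 6.25) < 1e-5

    def test_gain_scales_rate_multiplicatively(self):
        p = DMFParameters()
        for I in (0.2, 0.38, 0.6):
            base = transfer_rate(I, p.a_E, p.b_E, p.d_E, M=1.0)
            assert np.isclose(transfer_rate(I, p.a_E, p.b_E, p.d_E, M=0.5),
                              0.5 * base)
            assert np.isclose(transfer_rate(I, p.a_E, p.b_E, p.d_E, M=2.0),
                              2.0 * base)

    def test_monotone_in_current(self):
        p = DMFParameters()
        I = np.linspace(0.0, 1.0, 200)
        r = transfer_rate(I, p.a_E, p.b_E, p.d_E)
        assert np.all(np.diff(r) > 0)

    def test_positive_everywhere(self):
        p = DMFParameters()
        I = np.linspace(-1.0, 2.0, 100)
        assert np.all(transfer_rate(I, p.a_I, p.b_I, p.d_I) > 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            transfer_rate(0.4, 310.0, 125.0, 0.16, M=0.0)

    @given(st.floats(-0.5, 1.5), st.floats(0.01, 3.0))
    @hyp_settings(max_examples=50, deadline=None)
    def test_matches_direct_formula_away_from_singularity(self, I, M):
        p = DMFParameters()
        u = p.a_E * I - p.b_E
        if abs(p.d_E * u) < 1e-5:
            return
        expected = M * u / (1.0 - np.exp(-p.d_E * u))
        assert np.isclose(transfer_rate(I, p.a_E, p.b_E, p.d_E, M), expected,
                          rtol=1e-12)


class TestGainParameters:
    def test_constraint_violations(self):
        with pytest.raises(ValueError, match="s_I_abeta"):
            GainParameters(s_I_abeta=0.1).validate_constraints()
        with pytest.raises(ValueError, match="s_E_abeta"):
            GainParameters(s_E_abeta=-0.1).validate_constraints()
        with pytest.raises(ValueError, match="s_E_tau"):
            GainParameters(s_E_tau=0.1).validate_constraints()
        with pytest.raises(ValueError, match="b_I_tau"):
            GainParameters(b_I_tau=0.1).validate_constraints()

    def test_valid_parameters_pass(self):
        GainParameters(s_E_abeta=0.2, s_E_tau=-0.3, s_I_abeta=-0.25,
                       b_E_abeta=0.1).validate_constraints()

    def test_free_value_round_trip(self):
        gp = GainParameters(b_E_abeta=1, s_E_abeta=2, b_E_tau=3, s_E_tau=-4,
                            b_I_abeta=5, s_I_abeta=-6)
        assert GainParameters.from_free_values(gp.free_values()) == gp


class TestComputeGains:
    def test_polynomial_hand_value(self):
        ab = BurdenMap(np.array([2.0]), "abeta")
        ta = BurdenMap(np.array([3.0]), "tau")
        gp = GainParameters(b_E_abeta=0.1, s_E_abeta=0.2, b_E_tau=-0.1,
                            s_E_tau=-0.05, b_I_abeta=0.0, s_I_abeta=-0.1)
        M_E, M_I = compute_gains(ab, ta, gp)
        # (1 + 0.1 + 0.2*2) * (1 - 0.1 - 0.05*3) = 1.5 * 0.75
        assert np.isclose(M_E[0], 1.5 * 0.75)
        # (1 + 0 - 0.1*2) * 1
        assert np.isclose(M_I[0], 0.8)

    def test_homogeneous_limit_is_unity(self):
        ab = BurdenMap(np.array([1.0, 2.0]), "abeta")
        ta = BurdenMap(np.array([1.0, 2.0]), "tau")
        M_E, M_I = compute_gains(ab, ta, GainParameters())
        assert np.all(M_E == 1.0) and np.all(M_I == 1.0)

    def test_clamped_below(self):
        ab = BurdenMap(np.array([10.0]), "abeta")
        ta = BurdenMap(np.array([1.0]), "tau")
        M_E, M_I = compute_gains(ab, ta, GainParameters(s_I_abeta=-1.0))
        assert M_I[0] == GAIN_EPS

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            compute_gains(BurdenMap(np.ones(3)), BurdenMap(np.ones(4), "tau"),
                          GainParameters())


class TestCurrents:
    def test_hand_computed_two_nodes(self):
        w = np.array([[0.0, 0.5], [0.2, 0.0]])
        sc = StructuralConnectome(w)
        p = DMFParameters(G=2.0)
        fic = FICWeights(np.array([1.0, 1.5]))
        S_E = np.array([0.1, 0.2])
        S_I = np.array([0.05, 0.3])
        I_E, I_I = currents(S_E, S_I, sc, fic, p)
        c0 = 0.5 * 0.2  # input to node 0 from node 1
        exp_IE0 = 1.0 * 0.382 + 1.4 * 0.15 * 0.1 + 0.15 * 2.0 * c0 \
            - 1.0 * 0.05
        exp_II0 = 0.7 * 0.382 + 0.15 * 0.1 - 0.05
        assert np.isclose(I_E[0], exp_IE0)
        assert np.isclose(I_I[0], exp_II0)

    def test_shape_mismatch_rejected(self):
        sc = StructuralConnectome(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="dimensions"):
            currents(np.zeros(3), np.zeros(3), sc, FICWeights(np.ones(2)),
                     DMFParameters())


class TestIntegrate:
    def test_deterministic_given_seed(self, small_sc):
        p = DMFParameters(G=1.0)
        fic = FICWeights(np.ones(small_sc.n_regions))
        a = integrate(small_sc, fic, None, p, 500.0, seed=7)
        b = integrate(small_sc, fic, None, p, 500.0, seed=7)
        assert np.array_equal(a.S_E, b.S_E) and np.array_equal(a.r_E, b.r_E)

    def test_seed_changes_trajectory(self, small_sc):
        p = DMFParameters(G=1.0)
        fic = FICWeights(np.ones(small_sc.n_regions))
        a = integrate(small_sc, fic, None, p, 500.0, seed=7)
        b = integrate(small_sc, fic, None, p, 500.0, seed=8)
        assert not np.array_equal(a.S_E, b.S_E)

    def test_gating_bounded(self, small_sc):
        p = DMFParameters(G=1.0, sigma=0.05)
        fic = FICWeights(np.ones(small_sc.n_regions))
        sim = integrate(small_sc, fic, None, p, 2000.0, seed=1)
        for arr in (sim.S_E, sim.S_I):
            assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_store_every_stride(self, small_sc):
        p = DMFParameters()
        fic = FICWeights(np.ones(small_sc.n_regions))
        full = integrate(small_sc, fic, None, p, 100.0, seed=3)
        strided = integrate(small_sc, fic, None, p, 100.0, seed=3,
                            store_every=10)
        assert strided.S_E.shape[0] == 10
        assert np.array_equal(strided.S_E, full.S_E[::10])
        assert strided.dt == 10 * p.dt

    def test_noise_free_single_node_matches_ode_oracle(self, single_node_sc):
        """[DERIVED] sigma=0 Euler trajectory vs an adaptive-step ODE solver
        of the same vector field."""
        p = DMFParameters(sigma=0.0)
        fic = FICWeights(np.ones(1))
        sim = integrate(single_node_sc, fic, None, p, 2000.0, seed=0)

        def field(t, y):
            se, si = y
            I_E = p.W_E * p.I_0 + p.w_plus * p.J_N * se - 1.0 * si
            I_I = p.W_I * p.I_0 + p.J_N * se - si
            rE = transfer_rate(I_E, p.a_E, p.b_E, p.d_E)
            rI = transfer_rate(I_I, p.a_I, p.b_I, p.d_I)
            return [-se / p.tau_E + (1 - se) * p.gamma * rE,
                    -si / p.tau_I + rI / 1000.0]

        sol = solve_ivp(field, (0.0, 1999.0), [0.001, 0.001], rtol=1e-9,
                        atol=1e-12, dense_output=True)
        ref = sol.sol(np.arange(2000.0))
        # Euler at dt=1 ms: measured max deviation 2.8e-4 (S_E) / 1.3e-3
        # (S_I) during the initial fast transient, vanishing at steady state
        assert np.allclose(sim.S_E[:, 0], ref[0], atol=1e-3)
        assert np.allclose(sim.S_I[:, 0], ref[1], atol=3e-3)
        assert abs(sim.S_E[-1, 0] - ref[0][-1]) < 2e-5  # steady state tight

    def test_gain_vector_length_checked(self, small_sc):
        p = DMFParameters()
        fic = FICWeights(np.ones(small_sc.n_regions))
        with pytest.raises(ValueError, match="per region"):
            integrate(small_sc, fic, (np.ones(2), np.ones(2)), p, 100.0, 0)


class TestMeanRates:
    def test_matches_loop_average_of_integrate(self, small_sc):
        """[DERIVED] storage-free accumulator vs averaging stored rates."""
        p = DMFParameters(G=1.0)
        fic = FICWeights(np.ones(small_sc.n_regions))
        burn, window = 200.0, 800.0
        r_E, r_I = simulate_mean_rates(small_sc, fic, None, p, burn, window, 9)
        sim = integrate(small_sc, fic, None, p, burn + window, seed=9)
        assert np.allclose(r_E, sim.r_E[200:].mean(axis=0), rtol=1e-12)
        assert np.allclose(r_I, sim.r_I[200:].mean(axis=0), rtol=1e-12)


class TestCalibrateFic:
    def test_single_node_converges_near_three_hz(self, single_node_sc):
        p = DMFParameters()
        fic = calibrate_fic(single_node_sc, None, p, seed=2)
        assert fic.converged
        r_E, _ = simulate_mean_rates(single_node_sc, fic, None, p,
                                     2000.0, 10000.0, seed=2)
        assert abs(r_E[0] - 3.0) <= 0.2

    def test_weights_positive_and_history_recorded(self, small_sc):
        p = DMFParameters(G=1.0)
        fic = calibrate_fic(small_sc, None, p, seed=4)
        assert np.all(fic.J > 0)
        assert fic.rate_history.shape == (fic.n_iterations, small_sc.n_regions)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            FICWeights(np.array([1.0, 0.0]))
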
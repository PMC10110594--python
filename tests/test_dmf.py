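"""Model-level tests: F-I curve, currents, integration, FIC calibration."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from neuroentropy import (
    Connectome,
    InvalidParameterError,
    ModelParameters,
    SimulationState,
    calibrate_fic,
    compute_currents,
    em_step,
    neuromod_gain,
    simulate,
    transfer_rate,
)
from neuroentropy.dmf import CalibrationError, _run_kernel

P = ModelParameters()

# unit-gain excitatory F-I at I = 0.5 nA, evaluated independently with
# 30-digit arithmetic from the closed-form expression and frozen here
F_E_AT_0P5 = 30.3167201403191890701200697526
# inhibitory F-I at I = 0.35 nA, same provenance
F_I_AT_0P35 = 39.5642111112791992568379735170


class TestNeuromodGain:
    def test_zero_scaling_gives_unit_gain(self):
        d = np.array([0.0, 5.0, 20.0])
        np.testing.assert_array_equal(neuromod_gain(0.0, d), np.ones(3))

    def test_zero_density_region_unmodulated(self):
        g = neuromod_gain(0.025, np.array([0.0, 10.0]))
        assert g[0] == 1.0
        assert g[1] == pytest.approx(1.25)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            neuromod_gain(-0.1, np.array([1.0]))
        with pytest.raises(InvalidParameterError):
            neuromod_gain(0.1, np.array([-1.0]))


class TestTransferRate:
    def test_threshold_limit_is_inverse_shape(self):
        """At threshold the F-I curve takes its removable-singularity limit
        1/d, independent of the neuromodulatory gain."""
        for g_nm in (1.0, 1.3, 2.0):
            assert transfer_rate(P.I_thr_E, "E", g_nm) == pytest.approx(
                1.0 / P.d_E, abs=1e-9
            )
            assert transfer_rate(P.I_thr_I, "I", g_nm) == pytest.approx(
                1.0 / P.d_I, abs=1e-9
            )

    def test_matches_high_precision_evaluation(self):
        assert transfer_rate(0.5, "E", 1.0) == pytest.approx(F_E_AT_0P5, rel=1e-12)
        assert transfer_rate(0.35, "I", 1.0) == pytest.approx(F_I_AT_0P35, rel=1e-12)

    @pytest.mark.parametrize("population", ["E", "I"])
    @pytest.mark.parametrize("g_nm", [1.0, 1.5])
    def test_strictly_increasing_and_nonnegative(self, population, g_nm):
        I = np.linspace(-0.5, 1.5, 10_000)
        r = transfer_rate(I, population, g_nm)
        assert np.all(np.diff(r) > 0)
        assert np.all(r >= 0)

    def test_gain_steepens_the_curve_above_threshold(self):
        base = transfer_rate(0.5, "E", 1.0)
        assert transfer_rate(0.5, "E", 1.5) > base


def _state(n, J=1.0, seed=0, s_e=0.0, s_i=0.0):
    return SimulationState(
        S_E=np.full(n, s_e),
        S_I=np.full(n, s_i),
        J_fic=np.full(n, J),
        rng_state=np.random.default_rng(seed).bit_generator.state,
    )


class TestComputeCurrents:
    def test_resting_currents_from_external_drive(self):
        con = Connectome(weights=np.zeros((3, 3)))
        I_E, I_I = compute_currents(_state(3), con, P)
        np.testing.assert_allclose(I_E, P.W_E * P.I0)
        np.testing.assert_allclose(I_I, P.W_I * P.I0)
        assert I_E[0] == pytest.approx(0.382)
        assert I_I[0] == pytest.approx(0.2674)

    def test_local_recurrence_only(self):
        """With full excitatory gating and no coupling the excitatory current
        is the external drive plus the local recurrent loop."""
        con = Connectome(weights=np.zeros((2, 2)))
        st = _state(2, s_e=1.0, s_i=0.0)
        I_E, _ = compute_currents(st, con, P)
        assert I_E[0] == pytest.approx(0.382 + 1.4 * 0.15)

    def test_matches_naive_loop(self, rng):
        n = 3
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        con = Connectome(weights=w)
        st = SimulationState(
            S_E=rng.random(n), S_I=rng.random(n), J_fic=rng.random(n) + 0.5,
            rng_state=np.random.default_rng(0).bit_generator.state,
        )
        I_E, I_I = compute_currents(st, con, P)
        for i in range(n):
            long_range = sum(w[i, j] * st.S_E[j] for j in range(n))
            expected_E = (
                P.W_E * P.I0 + P.w_plus * P.J_NMDA * st.S_E[i]
                + P.G * P.J_NMDA * long_range - st.J_fic[i] * st.S_I[i]
            )
            expected_I = P.W_I * P.I0 + P.J_NMDA * st.S_E[i] - st.S_I[i]
            assert I_E[i] == pytest.approx(expected_E, rel=1e-12)
            assert I_I[i] == pytest.approx(expected_I, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        con = Connectome(weights=np.zeros((3, 3)))
        with pytest.raises(InvalidParameterError):
            compute_currents(_state(2), con, P)


class TestEmStep:
    def test_determinism(self, con10, rec10):
        a = em_step(_state(10, seed=5), con10, rec10, P, "5ht2a")
        b = em_step(_state(10, seed=5), con10, rec10, P, "5ht2a")
        np.testing.assert_array_equal(a.S_E, b.S_E)
        np.testing.assert_array_equal(a.S_I, b.S_I)

    def test_matches_kernel_without_noise(self, con10):
        """The vectorised step and the compiled kernel implement the same
        deterministic drift."""
        p0 = P.with_updates(sigma=0.0)
        n_steps = 50
        st = _state(10, J=1.5, s_e=0.3, s_i=0.2)
        for _ in range(n_steps):
            st = em_step(st, con10, None, p0, "placebo")
        _, S_E, S_I = _run_kernel(
            con10, np.full(10, 1.5), np.ones(10), p0,
            n_steps * p0.dt / 1000.0, seed=1,
            S_E0=np.full(10, 0.3), S_I0=np.full(10, 0.2),
        )
        np.testing.assert_allclose(st.S_E, S_E, atol=1e-12)
        np.testing.assert_allclose(st.S_I, S_I, atol=1e-12)

    def test_gating_stays_bounded_under_large_noise(self, con10, rec10):
        p_noisy = P.with_updates(sigma=0.5)
        st = _state(10, seed=3, s_e=0.5, s_i=0.5)
        for _ in range(200):
            st = em_step(st, con10, rec10, p_noisy, "5ht2a")
            assert np.all((st.S_E >= 0) & (st.S_E <= 1))
            assert np.all((st.S_I >= 0) & (st.S_I <= 1))

    def test_uncoupled_fixed_point_matches_root_finder(self):
        """With sigma=0 and G=0 the iterated dynamics settle on the
        self-consistent gating state solved independently from the drift."""
        p0 = P.with_updates(sigma=0.0, G=0.0)
        J = 1.2
        con = Connectome(weights=np.zeros((2, 2)))

        def drift(x):
            S_E, S_I = x
            I_E = p0.W_E * p0.I0 + p0.w_plus * p0.J_NMDA * S_E - J * S_I
            I_I = p0.W_I * p0.I0 + p0.J_NMDA * S_E - S_I
            r_E = transfer_rate(I_E, "E", 1.0, p0)
            r_I = transfer_rate(I_I, "I", 1.0, p0)
            return [
                -S_E / p0.tau_NMDA + (1 - S_E) * p0.gamma_kin * r_E * 1e-3,
                -S_I / p0.tau_GABA + r_I * 1e-3,
            ]

        expected = fsolve(drift, [0.2, 0.05], full_output=False)
        _, S_E, S_I = _run_kernel(
            con, np.full(2, J), np.ones(2), p0, 5.0, seed=1,
            S_E0=np.full(2, 0.1), S_I0=np.full(2, 0.1),
        )
        np.testing.assert_allclose(S_E, expected[0], atol=1e-6)
        np.testing.assert_allclose(S_I, expected[1], atol=1e-6)


class TestSimulate:
    def test_gain_identity(self, con10, rec10, cal10):
        """With zero neuromodulatory scaling the drug condition is bitwise
        identical to placebo for any seed."""
        p0 = P.with_updates(s_nm=0.0, t_total=6.0, t_burn=1.0)
        a = simulate(con10, rec10, p0, cal10.J_fic, "placebo", seed=99)
        b = simulate(con10, rec10, p0, cal10.J_fic, "5ht2a", seed=99)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_output_shape_contract(self, con10, rec10, cal10):
        p0 = P.with_updates(t_total=7.5, t_burn=2.0, record_dt=2.0)
        s = simulate(con10, rec10, p0, cal10.J_fic, "placebo", seed=1)
        assert s.rates.shape == (int(np.floor(5.5 * 1000 / 2.0)), 10)
        assert np.all(s.rates >= 0)

    def test_seed_reproducibility(self, con10, rec10, cal10):
        p0 = P.with_updates(t_total=6.0, t_burn=1.0)
        a = simulate(con10, rec10, p0, cal10.J_fic, "5ht2a", seed=4)
        b = simulate(con10, rec10, p0, cal10.J_fic, "5ht2a", seed=4)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_stationarity_of_mean_rates(self, con10, rec10, cal10):
        """Window means are stable in time: doubling the duration does not
        move any region's mean rate beyond run-to-run spread."""
        p_short = P.with_updates(t_total=32.0, t_burn=2.0)
        p_long = P.with_updates(t_total=62.0, t_burn=2.0)
        m_short = simulate(con10, rec10, p_short, cal10.J_fic, "placebo", seed=11).rates.mean(0)
        m_long = simulate(con10, rec10, p_long, cal10.J_fic, "placebo", seed=12).rates.mean(0)
        assert np.max(np.abs(m_short - m_long)) < 0.6


class TestCalibration:
    def test_symmetric_pair_gets_equal_weights(self, params):
        con = Connectome(weights=np.array([[0.0, 0.4], [0.4, 0.0]]))
        cal = calibrate_fic(con, None, params)
        assert abs(cal.J_fic[0] - cal.J_fic[1]) < 0.2
        assert np.all(np.abs(cal.achieved_rates - 3.0) <= 0.5)

    def test_uncoupled_regions_converge_to_same_weight(self, params):
        con = Connectome(weights=np.zeros((4, 4)))
        cal = calibrate_fic(con, None, params.with_updates(G=0.0))
        assert np.ptp(cal.J_fic) < 0.2

    def test_non_convergence_reports_worst_deviation(self, con10, params):
        with pytest.raises(CalibrationError) as err:
            calibrate_fic(con10, None, params, max_iter=1)
        assert err.value.worst_deviation > 0
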
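"""Exponential kinetics, tail currents, G-V/Boltzmann fits and energetics."""

import numpy as np
import pytest

from elkvdp import (
    BoltzmannFit,
    CurrentTrace,
    GVCurve,
    InvalidInputError,
    NoiseSpec,
    RecoveryCourse,
    boltzmann,
    build_gv,
    delta_g,
    fit_boltzmann,
    fit_exponential,
    fit_exponential_xy,
    fit_recovery_course,
    gen_gv_dataset,
    gen_recovery_course,
    measure_tail,
    prepulse_ddg,
    propagate,
    run_protocol_family,
    simulate_current,
)
from elkvdp.ephys import GAS_CONSTANT
from elkvdp.protocols import duration_family, gv_family


def _trace(t, y):
    return CurrentTrace(time=t, current=y, voltage=np.zeros_like(t))


class TestExponentialFit:
    def test_single_exponential_recovery(self):
        """Noiseless tau = 8.4 ms deactivation recovered to < 0.1%."""
        t = np.arange(0.0, 0.1, 1e-4)
        y = -2.0 * np.exp(-t / 0.0084) - 0.1
        fit = fit_exponential(_trace(t, y), (0.0, 0.1), n=1)
        assert fit.taus[0] == pytest.approx(0.0084, rel=1e-3)
        assert fit.amplitudes[0] == pytest.approx(-2.0, rel=1e-3)

    def test_double_exponential_recovery(self):
        """Generating tau1 = 4 ms, tau2 = 206 ms recovered to < 0.5%."""
        t = np.arange(0.0, 1.0, 1e-4)
        y = 0.1 + 0.5 * np.exp(-t / 0.004) + 1.2 * np.exp(-t / 0.206)
        fit = fit_exponential(_trace(t, y), (0.0, 1.0), n=2)
        assert fit.taus[0] == pytest.approx(0.004, rel=5e-3)
        assert fit.taus[1] == pytest.approx(0.206, rel=5e-3)
        assert fit.taus[0] < fit.taus[1]  # canonical ordering

    def test_translation_invariance(self):
        t = np.arange(0.0, 0.2, 1e-4)
        y = 1.0 + 0.8 * np.exp(-t / 0.02)
        a = fit_exponential_xy(t, y, n=1)
        b = fit_exponential_xy(t + 5.0, y, n=1)
        assert a.taus[0] == pytest.approx(b.taus[0], rel=1e-9)
        assert a.amplitudes[0] == pytest.approx(b.amplitudes[0], rel=1e-9)

    def test_constant_trace_flagged_degenerate(self):
        t = np.arange(0.0, 0.1, 1e-3)
        fit = fit_exponential(_trace(t, np.full_like(t, 3.0)), (0.0, 0.1), n=1)
        assert fit.degenerate
        assert fit.amplitudes[0] == pytest.approx(0.0, abs=1e-9)

    def test_window_too_short_rejected(self):
        t = np.arange(0.0, 0.1, 1e-3)
        with pytest.raises(InvalidInputError):
            fit_exponential(_trace(t, t), (0.0, 0.004), n=1)
        with pytest.raises(InvalidInputError):
            fit_exponential(_trace(t, t), (0.0, 0.1), n=3)


class TestTailMeasurement:
    def test_backextrapolation_matches_occupancy_truth(self, scheme):
        """Extrapolated tail equals g*P_open(tail_start)*(V_tail - E_rev)."""
        proto = gv_family(prepulse=False)
        for _, concrete in proto.expand()[7::2]:  # +20, +60, +100 mV
            occ = propagate(scheme, concrete)
            tr = simulate_current(occ, scheme)
            tail_start = concrete.epoch_start(2)
            idx = np.searchsorted(occ.time, tail_start)
            truth = scheme.conductance * occ.open_probability[idx] * (-100.0)
            meas = measure_tail(tr, tail_start)
            assert meas == pytest.approx(truth, rel=5e-3)
            assert meas < 0  # inward tail sign preserved

    def test_zero_open_probability_gives_zero(self, two_state):
        from elkvdp import VoltageProtocol

        # at E_rev the current is zero regardless of P_open
        proto = VoltageProtocol([(-100.0, 0.05), (0.0, 0.1)], dt=1e-4)
        occ = propagate(two_state, proto)
        tr = simulate_current(occ, two_state)
        assert measure_tail(tr, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_no_tail_epoch_rejected(self):
        t = np.arange(0.0, 0.1, 1e-3)
        with pytest.raises(InvalidInputError):
            measure_tail(_trace(t, t), tail_start=0.099)

    def test_tail_grows_with_pulse_duration(self, scheme):
        """Longer +60 mV pulses potentiate and enlarge the instantaneous tail."""
        traces = run_protocol_family(scheme, duration_family())
        tails = [abs(measure_tail(tr)) for tr in traces]
        assert all(b > a for a, b in zip(tails, tails[1:]))
        assert tails[-1] / tails[0] > 2


class TestGVAndBoltzmann:
    def test_gv_count_and_normalization(self, scheme):
        traces = run_protocol_family(scheme, gv_family(prepulse=False))
        gv = build_gv(traces)
        assert gv.voltages.size == 13
        norm = build_gv(traces, normalize=True)
        assert norm.amplitudes.max() == pytest.approx(1.0)

    def test_inconsistent_tail_voltages_rejected(self, scheme):
        traces = run_protocol_family(scheme, gv_family(prepulse=False))
        traces[0].meta["tail_voltage"] = -80.0
        with pytest.raises(InvalidInputError):
            build_gv(traces)

    def test_noiseless_boltzmann_recovery(self):
        """Generating V1/2 = -52.5 mV, Vs = 12 mV recovered to < 0.1%."""
        gv = gen_gv_dataset(v_half=-52.5, v_slope=12.0)
        fit = fit_boltzmann(gv)
        assert fit.v_half == pytest.approx(-52.5, rel=1e-3)
        assert fit.v_slope == pytest.approx(12.0, rel=1e-3)

    def test_midpoint_identity(self):
        fit = BoltzmannFit(i_min=0.1, i_max=1.1, v_half=-30.0, v_slope=15.0)
        assert fit.predict(-30.0) == pytest.approx(0.5 * (0.1 + 1.1))

    def test_fit_idempotence(self):
        """Refitting a curve generated from fitted parameters is a fixed point."""
        gv = gen_gv_dataset(v_half=-40.0, v_slope=9.0, i_max=2.0, i_min=0.2)
        fit1 = fit_boltzmann(gv)
        regenerated = GVCurve(gv.voltages, fit1.predict(gv.voltages), -100.0)
        fit2 = fit_boltzmann(regenerated)
        assert fit2.v_half == pytest.approx(fit1.v_half, rel=1e-6)
        assert fit2.v_slope == pytest.approx(fit1.v_slope, rel=1e-6)

    def test_normalization_invariance(self):
        """V1/2 and Vs are unchanged by linear rescaling of amplitudes."""
        gv = gen_gv_dataset(v_half=-52.5, v_slope=12.0)
        scaled = GVCurve(gv.voltages, 37.2 * gv.amplitudes, gv.tail_voltage)
        a, b = fit_boltzmann(gv), fit_boltzmann(scaled)
        assert b.v_half == pytest.approx(a.v_half, abs=1e-9)
        assert b.v_slope == pytest.approx(a.v_slope, abs=1e-9)

    def test_monte_carlo_midpoint_recovery(self):
        """2% noise, 50 replicates: mean V1/2 within 1 mV of truth."""
        fits = []
        for seed in range(1, 51):
            gv = gen_gv_dataset(
                v_half=-52.5, v_slope=12.0,
                noise=NoiseSpec("additive-gaussian", 0.02, seed),
            )
            fits.append(fit_boltzmann(gv).v_half)
        assert abs(np.mean(fits) - (-52.5)) < 1.0

    def test_too_few_points_rejected(self):
        gv = GVCurve(np.array([-80.0, -40.0, 0.0, 40.0]), np.array([0.0, 0.2, 0.8, 1.0]), -100.0)
        with pytest.raises(InvalidInputError):
            fit_boltzmann(gv)


class TestEnergetics:
    def test_delta_g_value(self):
        """dG = R*T*V1/2/Vs for the potentiated-midpoint parameters."""
        fit = BoltzmannFit(i_min=0.0, i_max=1.0, v_half=-52.5, v_slope=12.0)
        res = delta_g(fit, temperature=295.0)
        assert res.delta_g == pytest.approx(8.314 * 295.0 * (-52.5 / 12.0), rel=1e-12)
        assert res.delta_g == pytest.approx(-1.073e4, rel=1e-3)

    def test_zero_midpoint_gives_zero_energy(self):
        fit = BoltzmannFit(i_min=0.0, i_max=1.0, v_half=0.0, v_slope=12.0)
        assert delta_g(fit).delta_g == 0.0

    def test_linear_in_midpoint(self):
        f1 = BoltzmannFit(0.0, 1.0, -20.0, 12.0)
        f2 = BoltzmannFit(0.0, 1.0, -40.0, 12.0)
        assert delta_g(f2).delta_g == pytest.approx(2.0 * delta_g(f1).delta_g)

    def test_invalid_slope_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_g(BoltzmannFit(0.0, 1.0, -20.0, -5.0))

    def test_prepulse_ddg_signs(self):
        before = BoltzmannFit(0.0, 1.0, 20.0, 12.0)
        after = BoltzmannFit(0.0, 1.0, -40.0, 12.0)
        same = prepulse_ddg(before, before)
        assert same.dv_half == 0.0 and same.ddg_prepulse == 0.0
        shifted = prepulse_ddg(before, after)
        assert shifted.dv_half < 0 and shifted.ddg_prepulse < 0
        assert shifted.dv_half == pytest.approx(-60.0)
        expected = GAS_CONSTANT * 295.0 * (-40.0 - 20.0) / 12.0
        assert shifted.ddg_prepulse == pytest.approx(expected)


class TestRecoveryCourse:
    @pytest.mark.parametrize("tau_ms", [136.0, 293.0])
    def test_noiseless_tau_recovery(self, tau_ms):
        course = gen_recovery_course(tau_s=tau_ms / 1e3)
        fit = fit_recovery_course(course)
        assert fit.tau == pytest.approx(tau_ms / 1e3, rel=5e-3)
        assert not fit.flagged

    def test_empty_course_rejected(self):
        with pytest.raises(InvalidInputError):
            RecoveryCourse(np.array([]), np.array([]))
        with pytest.raises(InvalidInputError):
            fit_recovery_course(
                RecoveryCourse(np.array([0.0, 0.1, 0.2]), np.array([1.0, 0.5, 0.3]))
            )

    def test_nonmonotone_course_flagged(self):
        t = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([-55.0, -10.0, -45.0, -5.0, -40.0, 0.0])
        assert fit_recovery_course(RecoveryCourse(t, y)).flagged
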
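"""Gating-scheme construction, Q-matrix propagation and VDP kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from elkvdp import (
    ConfigError,
    GatingScheme,
    InvalidInputError,
    RateLaw,
    State,
    Transition,
    VoltageProtocol,
    build_generator,
    equilibrium_distribution,
    fit_exponential,
    propagate,
    rate_at_voltage,
    run_protocol_family,
    simulate_current,
    vdp_six_state,
)
from elkvdp.protocols import iv_family

from conftest import make_two_state


class TestRateLaw:
    @pytest.mark.parametrize(
        "k0,k1,v,expected",
        [
            (80.0, 0.025, 0.0, 80.0),
            (600.0, -0.025, 0.0, 600.0),
            (80.0, 0.025, 120.0, 80.0 * np.exp(3.0)),
            (60.0, 0.0, -100.0, 60.0),
        ],
    )
    def test_exponential_voltage_dependence(self, k0, k1, v, expected):
        assert rate_at_voltage(RateLaw(k0, k1), v) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_k0_and_nonfinite_voltage(self):
        with pytest.raises(InvalidInputError):
            RateLaw(-1.0)
        with pytest.raises(InvalidInputError):
            RateLaw(80.0, 0.025).rate(np.nan)

    def test_positive_for_all_finite_voltages(self):
        law = RateLaw(600.0, -0.025)
        for v in (-500.0, -120.0, 0.0, 120.0, 500.0):
            assert law.rate(v) > 0


class TestSchemeValidation:
    def test_duplicate_edge_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            GatingScheme(
                states=[State("A"), State("B")],
                transitions=[
                    Transition("A", "B", RateLaw(1.0)),
                    Transition("A", "B", RateLaw(2.0)),
                    Transition("B", "A", RateLaw(1.0)),
                ],
            )

    def test_missing_reverse_edge_rejected(self):
        with pytest.raises(ConfigError, match="reverse"):
            GatingScheme(
                states=[State("A"), State("B")],
                transitions=[Transition("A", "B", RateLaw(1.0))],
            )

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ConfigError, match="connected"):
            GatingScheme(
                states=[State("A"), State("B"), State("C"), State("D")],
                transitions=[
                    Transition("A", "B", RateLaw(1.0)),
                    Transition("B", "A", RateLaw(1.0)),
                    Transition("C", "D", RateLaw(1.0)),
                    Transition("D", "C", RateLaw(1.0)),
                ],
            )


class TestGenerator:
    @pytest.mark.parametrize("v", [-120.0, -40.0, 0.0, 60.0, 120.0])
    def test_columns_sum_to_zero(self, scheme, v):
        q = build_generator(scheme, v)
        # conservation to rounding precision at the matrix's own scale
        assert np.abs(q.sum(axis=0)).max() < 1e-12 * max(1.0, np.abs(q).max())
        assert np.all(np.diag(q) <= 0)

    def test_two_state_eigenvalues(self):
        q = build_generator(make_two_state(a=100.0, b=50.0), 0.0)
        eig = np.sort(np.linalg.eigvals(q).real)
        assert eig == pytest.approx([-150.0, 0.0], abs=1e-9)

    def test_nullspace_matches_long_propagation(self, scheme):
        """The Q-matrix null vector is the long-time limit of propagation."""
        p_eq = equilibrium_distribution(scheme, 0.0)
        start = np.zeros(scheme.n_states)
        start[0] = 1.0
        proto = VoltageProtocol([(0.0, 100.0)], dt=1.0)
        occ = propagate(scheme, proto, start)
        assert np.abs(occ.occupancy[-1] - p_eq).max() < 1e-6

    @pytest.mark.parametrize("v", [-100.0, 0.0, 60.0, 120.0])
    def test_detailed_balance_on_every_cycle(self, scheme, v):
        for ratio in scheme.cycle_flux_ratios(v):
            assert ratio == pytest.approx(1.0, abs=1e-9)


class TestPropagation:
    def test_two_state_matches_analytic_relaxation(self, two_state):
        """Closed-form p(t) = p_inf + (p0 - p_inf) exp(-(a+b)t)."""
        a, b = 100.0, 50.0
        proto = VoltageProtocol([(0.0, 0.05)], dt=1e-4)
        p0 = np.array([1.0, 0.0])
        occ = propagate(two_state, proto, p0)
        p_inf = a / (a + b)
        expected = p_inf + (0.0 - p_inf) * np.exp(-(a + b) * occ.time)
        assert np.abs(occ.occupancy[:, 1] - expected).max() < 1e-10

    def test_probability_conservation(self, scheme):
        proto = VoltageProtocol(
            [(-100.0, 0.05), (120.0, 0.3), (-100.0, 0.15)], dt=1e-4
        )
        occ = propagate(scheme, proto)
        assert occ.conservation_error() < 1e-9
        assert occ.occupancy.min() >= -1e-12
        assert occ.occupancy.max() <= 1.0 + 1e-12

    def test_matches_ode_oracle(self, scheme):
        """Matrix-exponential propagation agrees with adaptive ODE integration."""
        proto = VoltageProtocol(
            [(-100.0, 0.05), (120.0, 0.3), (-100.0, 0.15)], dt=1e-3
        )
        occ = propagate(scheme, proto)
        p0 = equilibrium_distribution(scheme, -100.0)
        edges = np.cumsum([0.0] + [d for _, d in proto.epochs])

        def rhs(t, p):
            i = min(np.searchsorted(edges, t, side="right") - 1, len(proto.epochs) - 1)
            return build_generator(scheme, proto.epochs[i][0]) @ p

        sol = solve_ivp(
            rhs, (0.0, occ.time[-1]), p0, t_eval=occ.time,
            rtol=1e-10, atol=1e-12, max_step=1e-3, method="LSODA",
        )
        assert np.abs(sol.y.T - occ.occupancy).max() < 1e-6

    def test_zero_duration_epoch_rejected(self):
        with pytest.raises(ConfigError):
            VoltageProtocol([(0.0, 0.0)], dt=1e-4)

    def test_bad_initial_distribution_rejected(self, scheme):
        proto = VoltageProtocol([(0.0, 0.01)], dt=1e-4)
        with pytest.raises(InvalidInputError):
            propagate(scheme, proto, np.array([0.5, 0.5, 0.5, 0.0, 0.0, 0.0]))


class TestCurrent:
    def test_ohmic_current_and_zero_conditions(self, two_state):
        proto = VoltageProtocol([(0.0, 0.02), (50.0, 0.02)], dt=1e-4)
        occ = propagate(two_state, proto)
        tr = simulate_current(occ, two_state)
        expected = occ.open_probability * (occ.voltage - two_state.e_rev)
        assert np.allclose(tr.current, expected)
        # zero whenever V = E_rev
        assert np.all(tr.current[occ.voltage == two_state.e_rev] == 0.0)

    def test_current_linear_in_conductance(self, two_state):
        proto = VoltageProtocol([(50.0, 0.02)], dt=1e-4)
        occ = propagate(two_state, proto)
        one = simulate_current(occ, two_state)
        two_state.conductance = 2.0
        double = simulate_current(occ, two_state)
        two_state.conductance = 1.0
        assert np.allclose(double.current, 2.0 * one.current)

    def test_state_count_mismatch_rejected(self, scheme, two_state):
        occ = propagate(two_state, VoltageProtocol([(0.0, 0.02)], dt=1e-4))
        with pytest.raises(InvalidInputError):
            simulate_current(occ, scheme)


class TestProtocolFamilies:
    def test_iv_family_counts_and_initial_condition(self, scheme):
        traces = run_protocol_family(scheme, iv_family())
        assert len(traces) == 13
        # every sweep starts from holding equilibrium: identical first sample
        first = {round(float(tr.current[0]), 12) for tr in traces}
        assert len(first) == 1

    def test_empty_family_rejected(self):
        with pytest.raises(ConfigError):
            VoltageProtocol(
                [(-100.0, 0.05), (0.0, 0.1)], dt=1e-4,
                variable_epoch=1, variable_values=[],
            )

    def test_biexponential_activation_at_plus120(self, scheme):
        """Depolarisation to +120 mV shows two well-separated relaxations."""
        traces = run_protocol_family(scheme, iv_family())
        tr = next(t for t in traces if t.meta["test_voltage"] == 120.0)
        fit = fit_exponential(tr, (0.051, 0.55), n=2)
        tau_fast, tau_slow = fit.taus
        assert tau_slow / tau_fast > 10

    def test_mode_shift_more_favorable_from_open_state(self, scheme):
        """Open-state mode equilibrium constant exceeds the closed-state one."""
        k_open = scheme.rate("O1", "O2", 0.0) / scheme.rate("O2", "O1", 0.0)
        k_closed = scheme.rate("C1", "C1p", 0.0) / scheme.rate("C1p", "C1", 0.0)
        assert k_open > k_closed


class TestSchemeConfig:
    def test_shipped_yaml_matches_programmatic_scheme(self, scheme):
        from elkvdp import load_scheme

        loaded = load_scheme()
        for v in (-100.0, 0.0, 60.0):
            assert np.allclose(
                build_generator(loaded, v), build_generator(scheme, v), rtol=1e-3
            )
        for ratio in loaded.cycle_flux_ratios(0.0):
            assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_rate_override(self, scheme):
        mod = scheme.with_rate("eps_r", 1.0)
        assert mod.rate("O2", "O1", 0.0) == 1.0
        with pytest.raises(ConfigError):
            scheme.with_rate("nonexistent", 1.0)
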
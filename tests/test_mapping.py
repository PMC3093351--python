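"""Parameter mapping: kernels, linearisation, closed form vs oracle,
reward search, policy readout, protocol table."""

import numpy as np
import pytest
from scipy import integrate

from spiketd.circuit import ArchitectureSpec, CircuitParams
from spiketd.mapping import (
    MappingParams,
    build_mapping,
    corresponding_reward_search,
    fit_linearization,
    integrate_transition,
    inverse_map,
    map_to_td,
    run_table1_protocol,
    transition_kernels,
    weights_to_policy,
)
from spiketd.plasticity import PlasticityRates, TraceParams

RATES = PlasticityRates(lambda_v=1e-3, lambda_p=2e-4, eta=0.05)


class TestKernels:
    def test_kernels_match_quadrature(self, spec2, circuit_params):
        """Closed forms against scipy quadrature of the defining
        integrals."""
        tr = circuit_params.traces
        tau_DA = circuit_params.tau_DA
        K = transition_kernels(tr, spec2, tau_DA)
        r_a = spec2.active_state_rate

        def gate(t):
            return r_a * np.exp(-t / tr.tau_pre) * (1 - np.exp(-t / tr.tau_e))

        K1_num, _ = integrate.quad(gate, 0, 5000)
        assert K.K_1 == pytest.approx(K1_num, rel=1e-6)
        K2_num, _ = integrate.quad(
            lambda t: gate(t) * np.exp(-t / tr.tau_post_str), 0, 5000
        )
        assert K.K_2 == pytest.approx(K2_num, rel=1e-6)

        S = spec2.n_da * tau_DA / 1000.0
        t0, t1 = K.t_on, K.t_on + K.T_ph

        def phi(t):
            if t < t0:
                return 0.0
            if t < t1:
                return S * (1 - np.exp(-(t - t0) / tau_DA))
            return S * (1 - np.exp(-K.T_ph / tau_DA)) * np.exp(-(t - t1) / tau_DA)

        KD_num, _ = integrate.quad(lambda t: gate(t) * phi(t), 0, 5000,
                                   limit=200)
        assert K.K_D == pytest.approx(KD_num, rel=1e-5)


class TestLinearization:
    def test_exact_line_recovered(self):
        dw = np.linspace(-40, 40, 9)
        u, c, resid = fit_linearization(dw, 0.17 * dw + 3.1)
        assert u == pytest.approx(0.17) and c == pytest.approx(3.1)
        assert resid < 1e-12

    def test_constant_table_zero_slope(self):
        u, c, _ = fit_linearization(np.array([-10.0, 0.0, 10.0]),
                                    np.array([2.0, 2.0, 2.0]))
        assert u == pytest.approx(0.0, abs=1e-12) and c == pytest.approx(2.0)

    def test_residual_guard(self):
        dw = np.linspace(-40, 40, 9)
        with pytest.raises(ValueError, match="residual"):
            fit_linearization(dw, dw**2, max_residual=1.0)

    def test_reward_curve_has_strictly_greater_slope(self, spec2,
                                                     circuit_params):
        """Mean-field amplitude curve: the slope of the linearisation is
        strictly greater with a reward DC present."""
        _, u0, _, amp = build_mapping(spec2, circuit_params,
                                      dw_range=(-40, 40))
        dws = np.linspace(-40, 40, 9)
        a_r = [amp(60 - d / 2, 60 + d / 2, 60.0) for d in dws]
        u_r, _, _ = fit_linearization(dws, np.array(a_r))
        assert u_r > u0 * 1.05


class TestMapToTD:
    def test_eta_zero_gives_gamma_one_exactly(self, mapping2):
        mp, u, c, _ = mapping2
        _, gamma, _ = map_to_td(u, c, PlasticityRates(eta=0.0), mp)
        assert gamma == 1.0

    def test_doubling_lambda_doubles_alpha_only(self, mapping2):
        mp, u, c, _ = mapping2
        a1, g1, o1 = map_to_td(u, c, RATES, mp)
        r2 = PlasticityRates(lambda_v=2e-3, lambda_p=2e-4, eta=0.05)
        a2, g2, o2 = map_to_td(u, c, r2, mp)
        assert a2 == pytest.approx(2 * a1)
        assert g2 == g1 and o2 == o1

    def test_closed_form_matches_ode_oracle_within_5pct(self, mapping2):
        """Criterion oracle at unit-test scale: closed-form value update vs
        brute-force integration across the fitted range."""
        mp, u, c, _ = mapping2
        alpha, gamma, o = map_to_td(u, c, RATES, mp)
        for dw in np.linspace(-40, 40, 9):
            wf, wt = 60 - dw / 2, 60 + dw / 2
            a_lin = u * dw + c
            dv_closed = alpha * (
                gamma * mp.value_of_weight(wt) - mp.value_of_weight(wf) + o
            )
            dv_oracle = mp.m * mp.k * integrate_transition(
                wf, wt, a_lin, RATES, mp
            )
            assert dv_closed == pytest.approx(
                dv_oracle, rel=0.05, abs=5e-4 * max(abs(dv_oracle), 1e-3)
            )

    def test_roundtrip_inverse_forward(self, mapping2):
        mp, u, c, _ = mapping2
        for alpha, gamma in [(0.1, 0.9), (0.05, 0.95), (0.2, 0.8)]:
            rates = inverse_map(alpha, gamma, u, mp)
            a2, g2, _ = map_to_td(u, c, rates, mp)
            assert a2 == pytest.approx(alpha, rel=0.05)
            assert g2 == pytest.approx(gamma, rel=0.05)

    def test_extrapolation_raises(self, mapping2):
        mp, _, _, _ = mapping2
        with pytest.raises(ValueError, match="outside"):
            mp.check_range(200.0)


class TestRewardSearch:
    def test_zero_dc_maps_to_zero_reward(self, spec2, circuit_params):
        r = corresponding_reward_search(0.0, spec2, circuit_params, RATES)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_monotone_and_sign(self, spec2, circuit_params):
        r_neg = corresponding_reward_search(-60.0, spec2, circuit_params, RATES)
        r_mid = corresponding_reward_search(30.0, spec2, circuit_params, RATES)
        r_pos = corresponding_reward_search(60.0, spec2, circuit_params, RATES)
        assert r_neg < 0 < r_mid < r_pos

    def test_negative_range_is_floor_compressed(self, spec2, circuit_params):
        """The tonic rate bounds the representation of punishments: doubling
        a large negative DC barely changes the mapped reward."""
        r1 = corresponding_reward_search(-60.0, spec2, circuit_params, RATES)
        r2 = corresponding_reward_search(-120.0, spec2, circuit_params, RATES)
        assert r2 < r1 < 0
        assert abs(r2) < 1.5 * abs(r1)


class TestWeightsToPolicy:
    def test_equal_weights_uniform_zero_arrow(self, spec2, circuit_params):
        p, arrow = weights_to_policy(np.full(4, 60.0), spec2, circuit_params)
        assert np.allclose(p, 0.25)
        assert arrow == (0.0, 0.0)

    def test_east_maximal_gives_eastward_arrow(self, spec2, circuit_params):
        w = np.full(4, 20.0)
        from spiketd.tasks import EAST

        w[EAST] = 100.0
        p, arrow = weights_to_policy(w, spec2, circuit_params)
        assert p[EAST] == p.max()
        assert arrow[0] == pytest.approx(p.max() - p.min())
        assert arrow[1] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_bounds_rejected(self, spec2, circuit_params):
        with pytest.raises(ValueError, match="bounds"):
            weights_to_policy(np.array([10.0, 60, 60, 60]), spec2,
                              circuit_params)


class TestProtocolTable:
    @pytest.fixture(scope="class")
    def table(self):
        return {(r.condition, r.eta_mode): r for r in run_table1_protocol()}

    @pytest.mark.parametrize("cond", [(0, 0, 0), (0, 1, 0), (0, 0, 1),
                                      (0, 1, 1), (1, 0, 0)])
    @pytest.mark.parametrize("mode", ["eta0", "eta+"])
    def test_silent_conditions_produce_no_change(self, table, cond, mode):
        assert table[(cond, mode)].direction == "none"

    def test_pre_post_baseline_dopamine(self, table):
        assert table[((1, 1, 0), "eta0")].direction == "none"
        assert table[((1, 1, 0), "eta+")].direction == "LTD"

    def test_dopamine_dependent_conditions(self, table):
        for mode in ("eta0", "eta+"):
            assert table[((1, 0, 1), mode)].direction == "dopamine-dependent"
            assert table[((1, 1, 1), mode)].direction == "dopamine-dependent"

    def test_crossover_is_higher_with_discount(self, table):
        c0 = table[((1, 1, 1), "eta0")].crossover
        c1 = table[((1, 1, 1), "eta+")].crossover
        assert c1 > c0
        # without post activity the crossover sits at the baseline for both
        assert table[((1, 0, 1), "eta+")].crossover == pytest.approx(c0,
                                                                     rel=1e-6)
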
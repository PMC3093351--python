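"""Traces, dopamine field and the two three-factor rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiketd.plasticity import (
    DopamineField,
    PlasticityRates,
    TraceParams,
    actor_weight_derivative,
    apply_bounds,
    dopamine_concentration,
    striatal_weight_derivative,
    update_activity_trace,
    update_efficacy_trace,
)


class TestActivityTrace:
    def test_pure_decay_closed_form(self):
        A = 3.7
        out = update_activity_trace(A, 0, dt=5.0, tau=50.0)
        assert out == pytest.approx(A * np.exp(-5.0 / 50.0))

    def test_zero_stays_zero(self):
        assert update_activity_trace(0.0, 0, 0.1, 50.0) == 0.0

    def test_steady_state_approximates_firing_rate(self):
        """Regular spiking at rate r: after t >> tau the trace oscillates
        around r within half an increment."""
        tau, dt, rate = 50.0, 0.1, 40.0
        isi = 1000.0 / rate
        A = 0.0
        vals = []
        for i in range(60_000):
            t = i * dt
            spike = abs((t + dt / 2) % isi) < dt
            A = update_activity_trace(A, int(spike), dt, tau)
            if t > 2000.0:
                vals.append(A)
        mean = np.mean(vals)
        assert abs(mean - rate) < 0.5 * 1000.0 / tau

    @given(st.floats(0, 100), st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_trace_stays_non_negative(self, A, spikes):
        assert update_activity_trace(A, spikes, 0.1, 50.0) >= 0


class TestEfficacyTrace:
    def test_one_is_fixed_point(self):
        assert update_efficacy_trace(1.0, False, 1.0, 500.0) == pytest.approx(1.0)

    def test_relaxation_one_tau_after_reset(self):
        E = 0.0  # just after a spike
        dt = 0.1
        for _ in range(5000):  # 500 ms = tau_e
            E = update_efficacy_trace(E, False, dt, 500.0)
        assert E == pytest.approx(1 - np.exp(-1), rel=1e-3)

    def test_sustained_firing_keeps_efficacy_low(self):
        """rate * tau_e >> 1 keeps E below 0.1 on average."""
        rng = np.random.default_rng(3)
        E, dt, tau_e = 1.0, 0.1, 500.0
        rate = 40.0  # rate * tau_e = 20 >> 1
        vals = []
        for i in range(50_000):
            spike = rng.random() < rate * dt / 1000.0
            E = update_efficacy_trace(E, spike, dt, tau_e)
            if i > 10_000:
                vals.append(E)
        assert np.mean(vals) < 0.1

    def test_bounded_in_unit_interval(self):
        E = 0.5
        for spike in (True, False, False, True, False):
            E = update_efficacy_trace(E, spike, 0.5, 500.0)
            assert 0.0 <= E <= 1.0


class TestDopamine:
    def test_no_spikes_zero(self):
        assert dopamine_concentration([], 100.0, 100.0) == 0.0

    def test_single_spike_kernel(self):
        tau = 100.0
        assert dopamine_concentration([0.0], tau, tau) == pytest.approx(np.exp(-1))

    def test_shot_noise_mean(self):
        """N neurons at rate rho: mean D = N * rho * tau (tau in s)."""
        rng = np.random.default_rng(7)
        N, rho, tau = 20, 5.0, 100.0
        T = 200_000.0
        spikes = np.sort(rng.uniform(0, T, size=rng.poisson(N * rho * T / 1000)))
        ts = np.linspace(T / 2, T, 200)
        D = [dopamine_concentration(spikes, t, tau) for t in ts]
        expected = N * rho * tau / 1000.0
        assert np.mean(D) == pytest.approx(expected, rel=0.1)

    def test_field_step_matches_direct_evaluation(self):
        field = DopamineField(tau_DA=100.0)
        spikes = [(5, 2), (17, 1), (40, 3)]  # (step, count)
        dt = 0.5
        counts = dict(spikes)
        for i in range(1, 101):
            field.step(counts.get(i, 0), dt)
        t = 100 * dt
        expected = sum(
            n * np.exp(-(t - s * dt) / 100.0) for s, n in spikes
        )
        assert field.D == pytest.approx(expected, rel=1e-9)


class TestWeightRules:
    R = PlasticityRates(lambda_v=1e-3, lambda_p=2e-4, eta=0.05)

    def test_no_pre_activity_no_change(self):
        assert striatal_weight_derivative(0.0, 1.0, 30.0, 99.0, 9.0, self.R) == 0.0

    def test_baseline_dopamine_eta0_neutral(self):
        R0 = PlasticityRates(lambda_v=1e-3, lambda_p=2e-4, eta=0.0)
        assert striatal_weight_derivative(40.0, 0.5, 30.0, 9.0, 9.0, R0) == 0.0

    def test_baseline_dopamine_with_post_trace_is_ltd_and_crossover(self):
        """eta > 0: baseline dopamine plus post activity depresses; the sign
        flips to potentiation once D exceeds b + eta * A_post."""
        b, A_post = 9.0, 30.0
        d_ltd = striatal_weight_derivative(40.0, 0.5, A_post, b, b, self.R)
        assert d_ltd < 0
        crossover = b + self.R.eta * A_post
        d_ltp = striatal_weight_derivative(40.0, 0.5, A_post, crossover + 1.0,
                                           b, self.R)
        assert d_ltp > 0
        assert striatal_weight_derivative(
            40.0, 0.5, A_post, crossover, b, self.R
        ) == pytest.approx(0.0, abs=1e-12)

    def test_actor_rule_requires_chosen_action_and_error(self):
        assert actor_weight_derivative(40.0, 0.5, 0.0, 20.0, 9.0, self.R) == 0.0
        assert actor_weight_derivative(40.0, 0.5, 10.0, 9.0, 9.0, self.R) == 0.0
        assert actor_weight_derivative(40.0, 0.5, 10.0, 20.0, 9.0, self.R) > 0

    def test_apply_bounds(self):
        assert apply_bounds(50.0, 20.0, 100.0) == 50.0
        assert apply_bounds(150.0, 20.0, 100.0) == 100.0
        assert apply_bounds(-3.0, 20.0, 100.0) == 20.0
        with pytest.raises(ValueError):
            apply_bounds(1.0, 5.0, 2.0)


class TestGatingWindow:
    def test_gating_product_peaks_after_state_exit(self):
        """Simulated visit: high pre rate for the dwell, then silence.

        The gating product A*E is temporally selective: smoothed over the
        trace time scale it peaks shortly *after* the exit, clearly exceeds
        its within-dwell average there, and has decayed to near zero well
        before a following transition (so plasticity credit is assigned to
        the most recently exited state).
        """
        tr = TraceParams()
        dt = 0.1
        rng = np.random.default_rng(11)
        dwell, total = 300.0, 1500.0
        A, E = 0.0, 1.0
        prod = []
        for i in range(int(total / dt)):
            t = i * dt
            rate = 40.0 if t < dwell else 0.0
            spike = rng.random() < rate * dt / 1000.0
            A = update_activity_trace(A, spike, dt, tr.tau_pre)
            E = update_efficacy_trace(E, spike, dt, tr.tau_e)
            prod.append(A * E)
        prod = np.array(prod)
        t_grid = np.arange(prod.size) * dt
        kernel = np.ones(int(50.0 / dt)) / int(50.0 / dt)
        smooth = np.convolve(prod, kernel, mode="same")
        post = smooth[(t_grid > dwell) & (t_grid < dwell + 300.0)].mean()
        entry = smooth[(t_grid > 0) & (t_grid < 50.0)].mean()
        dwell_mean = smooth[(t_grid > 50.0) & (t_grid < dwell)].mean()
        # the synapse stays sensitive through the phasic window after exit
        assert post > 0.5 * dwell_mean
        # entry is suppressed: the activity trace must build while the
        # efficacy trace is being reset
        assert entry < 0.5 * post
        # and the credit window closes before a following transition
        late = smooth[t_grid > dwell + 600.0]
        assert np.all(late < 0.05 * smooth.max())

    def test_zero_error_neutrality_over_history(self):
        """With D clamped to b and eta = 0, any stimulation history leaves
        the weight untouched."""
        R0 = PlasticityRates(lambda_v=1e-3, lambda_p=2e-4, eta=0.0)
        rng = np.random.default_rng(13)
        w, A, E = 60.0, 0.0, 1.0
        dt, b = 0.1, 9.0
        for _ in range(20_000):
            spike = rng.random() < 0.004
            A = update_activity_trace(A, spike, dt, 50.0)
            E = update_efficacy_trace(E, spike, dt, 500.0)
            w += dt * striatal_weight_derivative(A, E, 30.0, b, b, R0)
        assert w == 60.0
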
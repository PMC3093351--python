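"""Mapping between synaptic plasticity parameters and TD(0) parameters.

The net change of the mean cortico-striatal weight of a state's synapses
over one transition equals, after converting weights to value units, a
slightly modified TD(0) value update with self-adapting learning rate,
discount factor and offset.  The derivation integrates the plasticity rule

    dw/dt = lambda_v * A_pre(t) * E_pre(t) * (D(t) - b - eta * A_post(t))

over an idealised transition: the pre-synaptic pool fires at the active
rate until the exit at t = 0 and is silent afterwards, so

    A_pre(t) = r_a * exp(-t / tau_pre),
    E_pre(t) = 1 - exp(-t / tau_e),

the dopamine concentration carries a phasic population-rate excursion of
amplitude ``a`` (spikes/s per DA neuron) over the window
[t_on, t_on + T_ph], low-pass filtered by the uptake time constant, and the
post-synaptic (striatal) trace relaxes from the previous state's rate to
the new state's rate.  All three waveforms are sums of exponentials, so
every integral has a closed form; the constants

    K_D = int G(t) * Phi(t)/a dt      (gating x normalised dopamine kernel)
    K_1 = int G(t) dt
    K_2 = int G(t) * exp(-t/tau_post) dt,       G = A_pre * E_pre

depend only on the synaptic time constants and circuit timing.  With the
phasic amplitude linearised as ``a = u * dw + c`` over a weight-difference
range, and the value function identified with the striatal rate,
``V = m * rho``, ``rho = k * w + rho0`` (both linear fits over the allowed
weight range), the per-transition value change is

    dV = alpha * (gamma * V(s') - V(s) + o)

    alpha = lambda_v * (u * K_D + eta * k * K_2)
    gamma = (u * K_D - eta * k * (K_1 - K_2)) / (u * K_D + eta * k * K_2)
    o     = m * k * c * K_D / (u * K_D + eta * k * K_2)

``eta = 0`` gives ``gamma = 1`` exactly; scaling ``lambda_v`` scales
``alpha`` without touching ``gamma``.  Because ``u`` and ``c`` depend on
the weight-difference range and on the reward DC (the amplitude curve is
nonlinear and reward-dependent), the equivalent algorithm has
*self-adapting* parameters: the larger the value difference of successive
states, the larger the local slope ``u`` and hence the effective learning
rate and discount factor.

The module also provides the brute-force oracle (numerical integration of
the same idealised transition), the inverse mapping, the reward-search, the
weight-to-probability readout of the actor, and the plasticity-protocol
driver reproducing the sign table of the rule's predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .circuit import ArchitectureSpec, CircuitParams
from .plasticity import PlasticityRates, TraceParams
from .tasks import EAST, NORTH, SOUTH, WEST
from .transfer import InputStream, membrane_stats, rate_from_inputs

__all__ = [
    "MappingParams",
    "TransitionKernels",
    "ProtocolResult",
    "critic_rate_model",
    "fit_linearization",
    "transition_kernels",
    "map_to_td",
    "inverse_map",
    "integrate_transition",
    "corresponding_reward_search",
    "weights_to_policy",
    "run_table1_protocol",
]


# ---------------------------------------------------------------------------
# closed-form transition kernels
# ---------------------------------------------------------------------------

def _int_exp(coef: float, rate: float, t0: float, t1: float) -> float:
    """integral of coef * exp(-rate * t) over [t0, t1] (t1 may be inf)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    upper = 0.0 if np.isinf(t1) else np.exp(-rate * t1)
    return coef / rate * (np.exp(-rate * t0) - upper)


@dataclass(frozen=True)
class TransitionKernels:
    """The synaptic-time-constant constants of the mapping (ms units)."""

    K_D: float   # gating x unit-amplitude dopamine excursion
    K_1: float   # integral of the gating product
    K_2: float   # gating x post-trace filter
    r_active: float
    t_on: float
    T_ph: float


def transition_kernels(
    traces: TraceParams,
    spec: ArchitectureSpec,
    tau_DA: float,
    r_active: float | None = None,
    t_on: float | None = None,
) -> TransitionKernels:
    """Closed-form K_D, K_1, K_2 for the idealised transition."""
    r_a = spec.active_state_rate if r_active is None else r_active
    t0 = spec.d_indirect if t_on is None else t_on
    T_ph = spec.phasic_duration
    t1 = t0 + T_ph
    tp, te, tpost = traces.tau_pre, traces.tau_e, traces.tau_post_str
    gate_terms = [(r_a, 1.0 / tp), (-r_a, 1.0 / tp + 1.0 / te)]

    # K_1 and K_2
    K_1 = sum(_int_exp(c, r, 0.0, np.inf) for c, r in gate_terms)
    K_2 = sum(_int_exp(c, r + 1.0 / tpost, 0.0, np.inf) for c, r in gate_terms)

    # K_D: normalised dopamine excursion for a rate amplitude of 1 spike/s
    # per neuron: D jumps by 1 per spike and decays with tau_DA, so the
    # stationary increment is S = n_da * tau_DA / 1000 per unit rate.
    S = spec.n_da * tau_DA / 1000.0
    K_D = 0.0
    for c, r in gate_terms:
        # window [t0, t1]: S * (1 - exp(-(t - t0)/tau_DA))
        K_D += _int_exp(c * S, r, t0, t1)
        K_D += _int_exp(-c * S * np.exp(t0 / tau_DA), r + 1.0 / tau_DA, t0, t1)
        # tail t > t1: S * (1 - exp(-T_ph/tau_DA)) * exp(-(t - t1)/tau_DA)
        amp = S * (1.0 - np.exp(-T_ph / tau_DA)) * np.exp(t1 / tau_DA)
        K_D += _int_exp(c * amp, r + 1.0 / tau_DA, t1, np.inf)
    return TransitionKernels(K_D, K_1, K_2, r_a, t0, T_ph)


# ---------------------------------------------------------------------------
# amplitude model and linearisation
# ---------------------------------------------------------------------------

def critic_rate_model(spec: ArchitectureSpec, params: CircuitParams):
    """Mean-field model of the critic: striatal transfer and phasic
    amplitude.

    Returns ``(str_rate, amplitude)`` where ``str_rate(w)`` is the striatal
    stationary rate for an active-state cortico-striatal weight ``w`` and
    ``amplitude(w_from, w_to, reward_dc)`` the phasic deviation of the DA
    rate from its tonic value during the window in which the fast indirect
    pathway reports the new state while the delayed direct pathway still
    reports the old one.  The DA operating point is anchored to the tonic
    rate target, preserving the measured nonlinearity (convex near the low
    tonic rate, floored at zero rate) that makes the equivalent TD
    parameters self-adapting.
    """
    p = params
    tau_s = p.rise_time
    bg = InputStream(p.bg_rate, p.bg_amplitude)
    drive = spec.neurons_per_state * spec.active_state_rate

    def str_rate(w: float) -> float:
        return rate_from_inputs(
            p.neuron, 0.0, [bg, InputStream(drive, w)], tau_s
        )

    # DA input bookkeeping: inhibitory streams at their baseline rates set
    # the noise level; the operating-point DC is solved so that the tonic
    # rate matches the target.
    mid = 0.5 * (p.w_cs_min + p.w_cs_max)
    rho_mid = str_rate(mid)
    da_streams = [
        bg,
        InputStream(spec.n_striatum * rho_mid, p.w_critic_da),
        InputStream(spec.n_vp * p.vp_rate_target, p.w_critic_da),
    ]

    def tonic_of_dc(dc: float) -> float:
        return rate_from_inputs(p.neuron, dc, da_streams, tau_s)

    dc0 = optimize.brentq(
        lambda dc: tonic_of_dc(dc) - p.da_tonic_target, -2000.0, 4000.0
    )
    tonic = tonic_of_dc(dc0)
    # current per unit striatal rate difference along each pathway
    coupling = (
        abs(p.w_critic_da) * spec.n_striatum * np.e * (tau_s / 1000.0)
    )

    def amplitude(w_from: float, w_to: float, reward_dc: float = 0.0) -> float:
        d_i = coupling * (str_rate(w_to) - str_rate(w_from))
        return (
            rate_from_inputs(p.neuron, dc0 + d_i + reward_dc, da_streams,
                             tau_s)
            - tonic
        )

    return str_rate, amplitude


def fit_linearization(
    dw: np.ndarray, amp: np.ndarray, max_residual: float | None = None
) -> tuple[float, float, float]:
    """Least-squares line ``amp = u * dw + c``; returns (u, c, rms residual).

    Raises when the fit residual exceeds ``max_residual`` (the mapping is
    only valid where the amplitude curve is adequately linear).
    """
    dw = np.asarray(dw, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if dw.size < 2:
        raise ValueError("need at least two points")
    u, c = np.polyfit(dw, amp, 1)
    resid = float(np.sqrt(np.mean((u * dw + c - amp) ** 2)))
    if max_residual is not None and resid > max_residual:
        raise ValueError(
            f"linearisation residual {resid:.3g} exceeds {max_residual:.3g}"
        )
    return float(u), float(c), resid


# ---------------------------------------------------------------------------
# the mapping proper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingParams:
    """Constants converting synaptic quantities into value-function units."""

    m: float                 # value units per striatal spike/s
    k: float                 # striatal spikes/s per pA of weight
    rho0: float              # striatal rate at zero weight (linear fit)
    kernels: TransitionKernels
    traces: TraceParams
    tau_DA: float
    n_da: int
    w_ref: float = 60.0      # weight whose value is zero (the common init)
    dw_range: tuple[float, float] = (-80.0, 80.0)

    def value_of_weight(self, w) -> float:
        """V(w) = m * k * (w - w_ref): equal initial weights <=> V = 0."""
        return self.m * self.k * (np.asarray(w, dtype=float) - self.w_ref)

    def check_range(self, dw: float) -> None:
        lo, hi = self.dw_range
        if not lo - 1e-9 <= dw <= hi + 1e-9:
            raise ValueError(
                f"dw = {dw:.3g} outside the fitted range [{lo:.3g}, {hi:.3g}]"
            )


def map_to_td(
    u: float,
    c: float,
    rates: PlasticityRates,
    mp: MappingParams,
) -> tuple[float, float, float]:
    """(alpha, gamma, offset) of the equivalent discrete-time algorithm."""
    K = mp.kernels
    denom = u * K.K_D + rates.eta * mp.k * K.K_2
    if denom <= 0:
        raise ValueError("degenerate mapping: non-positive effective slope")
    alpha = rates.lambda_v * denom
    gamma = (u * K.K_D - rates.eta * mp.k * (K.K_1 - K.K_2)) / denom
    # with the value anchor V(w_ref) = 0 the eta term contributes the
    # striatal rate at the reference weight to the offset
    rho_ref = mp.k * mp.w_ref + mp.rho0
    offset = mp.m * mp.k * (c * K.K_D - rates.eta * K.K_1 * rho_ref) / denom
    return float(alpha), float(gamma), float(offset)


def inverse_map(
    alpha: float,
    gamma: float,
    u: float,
    mp: MappingParams,
    lambda_v_only: bool = False,
) -> PlasticityRates:
    """Synaptic (lambda_v, eta) realising a requested (alpha, gamma).

    ``gamma = 1`` requires ``eta = 0``; smaller discounts need a positive
    post-trace coefficient.  The learning-rate factor then follows from
    ``alpha``.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    K = mp.kernels
    if gamma == 1.0 or lambda_v_only:
        eta = 0.0
    else:
        # gamma = (u K_D - eta k (K1 - K2)) / (u K_D + eta k K2)
        eta = u * K.K_D * (1.0 - gamma) / (
            mp.k * (K.K_1 - K.K_2 + gamma * K.K_2)
        )
    denom = u * K.K_D + eta * mp.k * K.K_2
    lam = alpha / denom
    return PlasticityRates(lambda_v=lam, lambda_p=lam, eta=eta)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def integrate_transition(
    w_from: float,
    w_to: float,
    amplitude: float,
    rates: PlasticityRates,
    mp: MappingParams,
    dt: float = 0.05,
    horizon: float = 5000.0,
) -> float:
    """Net weight change over one idealised transition, by numerical
    integration of the plasticity ODE (independent of the closed forms)."""
    K = mp.kernels
    tr_t = np.arange(0.0, horizon, dt)
    A_pre = K.r_active * np.exp(-tr_t / mp.traces.tau_pre)
    E_pre = 1.0 - np.exp(-tr_t / mp.traces.tau_e)
    rho_from = mp.k * w_from + mp.rho0
    rho_to = mp.k * w_to + mp.rho0
    A_post = rho_to + (rho_from - rho_to) * np.exp(
        -tr_t / mp.traces.tau_post_str
    )
    # dopamine deviation: filtered rectangular rate excursion
    tau_DA = mp.tau_DA
    S = mp.n_da * tau_DA / 1000.0 * amplitude
    t0, t1 = K.t_on, K.t_on + K.T_ph
    Ddev = np.zeros_like(tr_t)
    win = (tr_t >= t0) & (tr_t < t1)
    Ddev[win] = S * (1.0 - np.exp(-(tr_t[win] - t0) / tau_DA))
    tail = tr_t >= t1
    Ddev[tail] = (
        S * (1.0 - np.exp(-K.T_ph / tau_DA))
        * np.exp(-(tr_t[tail] - t1) / tau_DA)
    )
    integrand = rates.lambda_v * A_pre * E_pre * (
        Ddev - rates.eta * A_post
    )
    return float(np.trapezoid(integrand, tr_t))


def build_mapping(
    spec: ArchitectureSpec,
    params: CircuitParams,
    dw_range: tuple[float, float] = (-80.0, 80.0),
    n_grid: int = 9,
    reward_dc: float = 0.0,
    value_span: float = 2.0,
):
    """Fit the full mapping from the mean-field critic model.

    Returns ``(mp, u, c, amplitude_fn)``: the mapping constants, the fitted
    linearisation of the amplitude curve for the given reward DC over
    ``dw_range``, and the underlying amplitude function.  ``value_span``
    fixes the arbitrary value-unit scale ``m`` so that the allowed
    cortico-striatal weight range spans that many value units.
    """
    str_rate, amplitude = critic_rate_model(spec, params)
    w_lo, w_hi = params.w_cs_min, params.w_cs_max
    wgrid = np.linspace(w_lo, w_hi, 13)
    rho = np.array([str_rate(w) for w in wgrid])
    k, rho0 = np.polyfit(wgrid, rho, 1)
    m = value_span / (k * (w_hi - w_lo))

    kern = transition_kernels(params.traces, spec, params.tau_DA)
    mp = MappingParams(m=float(m), k=float(k), rho0=float(rho0),
                       kernels=kern, traces=params.traces,
                       tau_DA=params.tau_DA, n_da=spec.n_da,
                       w_ref=params.w_cs_init, dw_range=dw_range)

    # amplitude table over the dw range (mid-anchored weight pairs)
    dws = np.linspace(dw_range[0], dw_range[1], n_grid)
    mid = 0.5 * (w_lo + w_hi)
    table = []
    for dw in dws:
        wf = np.clip(mid - dw / 2.0, w_lo, w_hi)
        wt = np.clip(wf + dw, w_lo, w_hi)
        wf = wt - dw
        table.append(amplitude(wf, wt, reward_dc))
    u, c, _ = fit_linearization(dws, np.asarray(table))
    return mp, u, c, amplitude


def corresponding_reward_search(
    reward_dc: float,
    spec: ArchitectureSpec,
    params: CircuitParams,
    rates: PlasticityRates,
    dw_range: tuple[float, float] = (-40.0, 40.0),
    tol: float = 1e-6,
) -> float:
    """Scalar reward for the discrete agent equivalent to a reward DC.

    Matches, at zero weight difference, the extra per-transition value
    change that the reward DC produces in the spiking rule (computed with
    the ODE oracle) against the discrete update ``alpha * r``; solved by
    bisection on ``r``.
    """
    mp, u0, c0, amplitude = build_mapping(spec, params, dw_range=dw_range)
    alpha, _, _ = map_to_td(u0, c0, rates, mp)
    mid = 0.5 * (params.w_cs_min + params.w_cs_max)
    a_plain = amplitude(mid, mid, 0.0)
    a_reward = amplitude(mid, mid, reward_dc)
    dv_extra = mp.m * mp.k * (
        integrate_transition(mid, mid, a_reward, rates, mp)
        - integrate_transition(mid, mid, a_plain, rates, mp)
    )
    # bisection on f(r) = alpha * r - dv_extra (monotone in r)
    scale = max(abs(dv_extra) / alpha, 1.0)
    lo, hi = -10.0 * scale, 10.0 * scale
    f = lambda r: alpha * r - dv_extra
    if f(lo) * f(hi) > 0:
        raise RuntimeError("reward search failed to bracket a solution")
    for _ in range(200):
        mid_r = 0.5 * (lo + hi)
        if f(lo) * f(mid_r) <= 0:
            hi = mid_r
        else:
            lo = mid_r
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# actor weight -> probability readout
# ---------------------------------------------------------------------------

def weights_to_policy(
    actor_weights: np.ndarray,
    spec: ArchitectureSpec,
    params: CircuitParams,
    n_replicas: int = 4000,
    seed: int = 2024,
    t_max: float = 600.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Action probabilities and preferred-direction arrow for one state.

    After each choice the actor neurons are hyperpolarised together, so the
    next selection is a synchronised first-passage race from the
    post-inhibition membrane state.  The race is modelled in the diffusion
    approximation: each actor's free membrane potential is an
    Ornstein-Uhlenbeck process with the mean and variance implied by its
    cortical drive, started at the inhibited level, and the first actor to
    cross threshold wins.  This model is independent of the spiking engine
    (no synapse kernels, no network) and is validated against the full
    first-spike simulation.  Probabilities of actions with identical
    weights are averaged, so exact ties give exactly equal probabilities.
    The arrow is ``(P(east) - P(west), P(north) - P(south))``.
    """
    w = np.asarray(actor_weights, dtype=float)
    if w.shape != (spec.n_actions,):
        raise ValueError("one weight per action expected")
    if np.any(w < params.w_ca_min - 1e-9) or np.any(w > params.w_ca_max + 1e-9):
        raise ValueError("actor weights outside the configured bounds")
    p_neuron = params.neuron
    bg = InputStream(params.bg_rate, params.bg_amplitude)
    drive = spec.neurons_per_state * spec.active_state_rate
    mus, sigs = [], []
    for wi in w:
        mu, s = membrane_stats(p_neuron, 0.0,
                               [bg, InputStream(drive, wi)],
                               params.rise_time)
        mus.append(mu)
        sigs.append(s)
    mus = np.array(mus)
    sigs = np.array(sigs)

    rng = np.random.default_rng(seed)
    dt = 0.1
    n_a = w.size
    v0 = mus + p_neuron.R_m * params.dc_actor_inhib
    V = np.tile(v0, (n_replicas, 1))
    decay = np.exp(-dt / p_neuron.tau_m)
    noise = sigs * np.sqrt(1.0 - decay**2)
    crossing = np.full((n_replicas, n_a), np.inf)
    active = np.ones((n_replicas, n_a), dtype=bool)
    t = 0.0
    while t < t_max and active.any():
        t += dt
        V = mus + (V - mus) * decay + noise * rng.standard_normal(
            (n_replicas, n_a)
        )
        hit = active & (V >= p_neuron.V_th)
        crossing[hit] = t
        active &= ~hit
    if not np.isfinite(crossing.min(axis=1)).all():
        raise RuntimeError("actor race undecided within the horizon")
    winners = np.argmin(crossing, axis=1)
    p = np.bincount(winners, minlength=n_a) / n_replicas
    # exact ties share the average probability of their group
    for wi in np.unique(w):
        group = w == wi
        p[group] = p[group].mean()
    p = p / p.sum()
    arrow = (float(p[EAST] - p[WEST]), float(p[NORTH] - p[SOUTH]))
    return p, arrow


# ---------------------------------------------------------------------------
# plasticity-protocol driver (sign table of the rule's predictions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolResult:
    condition: tuple[int, int, int]   # (pre, post, dopa)
    eta_mode: str                     # "eta0" (gamma = 1) or "eta+" (gamma < 1)
    direction: str                    # LTP / LTD / none / dopamine-dependent
    crossover: float | None = None    # concentration of the LTD->LTP switch


def _protocol_dw(
    pre: int, post: int, D_level: float, b: float,
    rates: PlasticityRates, traces: TraceParams,
    rate_hz: float = 40.0, t_active: float = 500.0,
    horizon: float = 2000.0, dt: float = 0.1,
) -> float:
    """Net weight change of one scripted conditioning episode.

    Pre/post populations fire regularly at ``rate_hz`` during the first
    ``t_active`` ms when their flag is set; the dopamine concentration is
    clamped to ``D_level`` throughout (baseline ``b``).
    """
    t = np.arange(0.0, horizon, dt)
    spikes_pre = np.zeros_like(t, dtype=bool)
    spikes_post = np.zeros_like(t, dtype=bool)
    if pre:
        isi = 1000.0 / rate_hz
        times = np.arange(isi, t_active, isi)
        spikes_pre[np.searchsorted(t, times)] = True
    if post:
        isi = 1000.0 / rate_hz
        times = np.arange(isi, t_active, isi)
        spikes_post[np.searchsorted(t, times)] = True
    A_pre = 0.0
    E_pre = 1.0
    A_post = 0.0
    dec_p = np.exp(-dt / traces.tau_pre)
    dec_e = np.exp(-dt / traces.tau_e)
    dec_s = np.exp(-dt / traces.tau_post_str)
    dw = 0.0
    for i in range(t.size):
        A_pre = A_pre * dec_p + spikes_pre[i] * (1000.0 / traces.tau_pre)
        E_pre = 0.0 if spikes_pre[i] else 1.0 + (E_pre - 1.0) * dec_e
        A_post = A_post * dec_s + spikes_post[i] * (1000.0 / traces.tau_post_str)
        dw += dt * rates.lambda_v * A_pre * E_pre * (
            D_level - b - rates.eta * A_post
        )
    return dw


def run_table1_protocol(
    traces: TraceParams | None = None,
    eta_pos: float = 0.05,
    b: float = 9.0,
    dopa_excursion: float = 30.0,
    lambda_v: float = 1e-3,
) -> list[ProtocolResult]:
    """Direction of plasticity for all 8 pre/post/dopamine conditions.

    ``dopa = 0`` clamps the concentration to the baseline ``b``; ``dopa =
    1`` sweeps the concentration from far below to far above baseline and
    reports either a fixed direction or "dopamine-dependent" together with
    the LTD-to-LTP crossover concentration.  Run for both the undiscounted
    rule (eta = 0) and the discounted one (eta > 0); with eta > 0 and
    conjoint pre/post activity the crossover lies strictly above baseline,
    so baseline dopamine plus pre+post activity yields LTD.
    """
    traces = traces or TraceParams()
    results: list[ProtocolResult] = []
    tiny = 1e-6
    for eta_mode, eta in (("eta0", 0.0), ("eta+", eta_pos)):
        rates = PlasticityRates(lambda_v=lambda_v, lambda_p=lambda_v, eta=eta)
        for pre in (0, 1):
            for post in (0, 1):
                for dopa in (0, 1):
                    if dopa == 0:
                        dw = _protocol_dw(pre, post, b, b, rates, traces)
                        scale = abs(
                            _protocol_dw(1, 0, b + dopa_excursion, b, rates,
                                         traces)
                        )
                        if abs(dw) < tiny * max(scale, 1.0):
                            direction = "none"
                        else:
                            direction = "LTD" if dw < 0 else "LTP"
                        results.append(ProtocolResult(
                            (pre, post, dopa), eta_mode, direction))
                    else:
                        levels = b + np.linspace(-dopa_excursion,
                                                 dopa_excursion, 41)
                        dws = np.array([
                            _protocol_dw(pre, post, L, b, rates, traces)
                            for L in levels
                        ])
                        scale = np.abs(dws).max()
                        if scale < tiny:
                            results.append(ProtocolResult(
                                (pre, post, dopa), eta_mode, "none"))
                            continue
                        neg = dws < -tiny * scale
                        pos = dws > tiny * scale
                        if neg.any() and pos.any():
                            # crossover concentration by sign change
                            idx = int(np.argmax(pos))
                            x0, x1 = levels[idx - 1], levels[idx]
                            y0, y1 = dws[idx - 1], dws[idx]
                            cross = x0 - y0 * (x1 - x0) / (y1 - y0)
                            results.append(ProtocolResult(
                                (pre, post, dopa), eta_mode,
                                "dopamine-dependent", float(cross)))
                        elif pos.any():
                            results.append(ProtocolResult(
                                (pre, post, dopa), eta_mode, "LTP"))
                        elif neg.any():
                            results.append(ProtocolResult(
                                (pre, post, dopa), eta_mode, "LTD"))
                        else:
                            results.append(ProtocolResult(
                                (pre, post, dopa), eta_mode, "none"))
    return results
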
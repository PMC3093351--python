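"""Trace-based three-factor plasticity with a global dopamine signal.

Each plastic synapse sees three local quantities and one global one:

* pre-synaptic **activity trace** ``A_pre`` -- a low-pass filter of the
  pre-synaptic spike train, incremented by ``1000 / tau_pre`` per spike and
  decaying with ``tau_pre`` (ms), so that its stationary mean equals the
  pre-synaptic firing rate in spikes/s;
* pre-synaptic **efficacy trace** ``E_pre`` -- reset to 0 at every
  pre-synaptic spike and relaxing exponentially to 1 with the long time
  constant ``tau_e``.  The product ``A_pre * E_pre`` is negligible while the
  pre-synaptic neuron fires steadily and peaks in the window just after the
  firing stops, confining plasticity to the period after the agent exits
  the state the neuron represents;
* post-synaptic **activity trace** ``A_post`` -- same dynamics as ``A_pre``,
  driven by the post-synaptic spike train;
* the global **dopamine concentration** ``D`` -- the superposition of
  unit-increment exponential kernels (uptake time constant ``tau_DA``) over
  the spikes of all dopaminergic neurons, compared against a fixed baseline
  ``b`` calibrated during a stimulus-free warm-up.

Weight dynamics (value-function synapses, cortex -> striatum):

    dw/dt = lambda_v * A_pre * E_pre * (D - b - eta * A_post)

with ``eta = 0`` recovering the undiscounted rule.  The ``eta`` term
converts the amplitude dependence on the *total* value of the new state
into a discounted one, playing the role of the discount factor of the
equivalent TD(0) algorithm (the exact correspondence is established in
:mod:`spiketd.mapping`).

Policy synapses (cortex -> actor):

    dw/dt = lambda_p * A_pre * E_pre * A_post * (D - b)

where ``A_post`` now flags the most recently chosen action.  Both rules are
integrated with forward Euler every time step and hard-clipped to their
configured bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraceParams",
    "PlasticityRates",
    "PlasticSynapseState",
    "DopamineField",
    "update_activity_trace",
    "update_efficacy_trace",
    "dopamine_concentration",
    "striatal_weight_derivative",
    "actor_weight_derivative",
    "apply_bounds",
]


@dataclass(frozen=True)
class TraceParams:
    tau_pre: float = 50.0       # ms; decays within one state dwell
    tau_e: float = 500.0        # ms; must be >> tau_pre
    tau_post_str: float = 100.0  # ms; striatal post trace (choice not critical)
    tau_post_act: float = 100.0  # ms; actor post trace, < typical dwell time

    def __post_init__(self) -> None:
        for name in ("tau_pre", "tau_e", "tau_post_str", "tau_post_act"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_e <= self.tau_pre:
            raise ValueError("tau_e must be large compared to tau_pre")


@dataclass(frozen=True)
class PlasticityRates:
    """Learning-rate factors; eta = 0 recovers the undiscounted rule."""

    lambda_v: float = 1e-3
    lambda_p: float = 2e-4
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_v <= 0 or self.lambda_p <= 0:
            raise ValueError("lambda factors must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class PlasticSynapseState:
    """State of one plastic synapse (scalar fields, used in unit protocols).

    Network simulations keep these quantities in arrays (one activity /
    efficacy trace per neuron, one weight per synapse); this container
    exists for single-synapse protocols and tests.
    """

    w: float
    A_pre: float = 0.0
    E_pre: float = 1.0
    A_post: float = 0.0


def update_activity_trace(A, n_spikes, dt: float, tau: float):
    """One Euler-exact step of the activity-trace filter.

    ``A`` decays with ``tau`` (ms) and gains ``1000 / tau`` per spike so the
    stationary mean of the trace equals the firing rate in spikes/s.
    Accepts scalars or arrays (``n_spikes`` = spikes since last step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return A * np.exp(-dt / tau) + np.asarray(n_spikes) * (1000.0 / tau)


def update_efficacy_trace(E, spiked, dt: float, tau_e: float):
    """Efficacy trace: relax toward 1 with ``tau_e``; reset to 0 on a spike."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    E = 1.0 + (E - 1.0) * np.exp(-dt / tau_e)
    return np.where(np.asarray(spiked, dtype=bool), 0.0, E)


def dopamine_concentration(spike_times, t: float, tau_DA: float) -> float:
    """Dopamine concentration at time ``t`` from a list of DA spike times.

    Each dopaminergic spike contributes a unit-increment exponential kernel
    with the uptake time constant ``tau_DA`` (ms): for a population of N
    neurons firing at rho spikes/s the mean concentration is
    ``N * rho * tau_DA / 1000``.
    """
    if tau_DA <= 0:
        raise ValueError("tau_DA must be positive")
    ts = np.asarray(spike_times, dtype=float)
    ts = ts[ts <= t]
    return float(np.exp(-(t - ts) / tau_DA).sum())


@dataclass
class DopamineField:
    """Global scalar dopamine concentration, updated per simulation step."""

    tau_DA: float = 100.0   # ms; striatal dopamine uptake time scale
    b: float = 0.0          # baseline concentration (calibrated)
    D: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_DA <= 0:
            raise ValueError("tau_DA must be positive")

    def step(self, n_da_spikes: int, dt: float) -> float:
        self.D = self.D * np.exp(-dt / self.tau_DA) + n_da_spikes
        return self.D

    def error(self) -> float:
        """Deviation of the concentration from its baseline."""
        return self.D - self.b


def striatal_weight_derivative(
    A_pre, E_pre, A_post, D: float, b: float, rates: PlasticityRates
):
    """dw/dt of a cortico-striatal (value) synapse; eta = 0 gives the
    undiscounted rule."""
    return rates.lambda_v * A_pre * E_pre * (D - b - rates.eta * A_post)


def actor_weight_derivative(
    A_pre, E_pre, A_post, D: float, b: float, rates: PlasticityRates
):
    """dw/dt of a cortex->actor (policy) synapse."""
    return rates.lambda_p * A_pre * E_pre * A_post * (D - b)


def apply_bounds(w, w_min: float, w_max: float):
    """Hard clipping of synaptic weights to [w_min, w_max]."""
    if w_min > w_max:
        raise ValueError("w_min must not exceed w_max")
    return np.clip(w, w_min, w_max)
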
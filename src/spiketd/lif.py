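"""Clock-driven simulation of current-based leaky integrate-and-fire neurons.

Neurons obey

    tau_m dV/dt = -(V - E_rest) + R_m * I(t),      R_m = tau_m / C_m

with a hard threshold V_th, reset to V_reset and an absolute refractory
period t_ref.  Each presynaptic spike arriving over a projection with peak
amplitude ``w`` (pA) and rise time ``tau_s`` contributes an alpha-shaped
post-synaptic current

    i(t) = w * e * (t / tau_s) * exp(-t / tau_s),   t >= 0,

which peaks at ``w`` a lag ``tau_s`` after arrival.  The linear system
(y1, y2, V) -- where y2 is the total synaptic current -- is advanced with
the exact matrix-exponential propagator, so the integration is stable for
any step that divides the transmission delays.  Threshold crossings are
detected at step boundaries.

Delays are realised as ring buffers in units of the time step; delays that
are not integer multiples of dt are rounded with a warning.  Poisson
background noise is delivered as spike trains through a per-population
background projection; each population owns an independent random stream
derived deterministically from the master seed and the population name, so
resizing one population never reshuffles the noise of another.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "NeuronParams",
    "ProjectionParams",
    "StimulusSpec",
    "alpha_psc",
    "poisson_background",
    "lif_rate_dc",
    "Network",
    "Simulation",
    "run_network",
]


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one LIF population (ms, pF, mV)."""

    tau_m: float = 10.0
    C_m: float = 250.0
    V_th: float = -55.0
    V_reset: float = -70.0
    t_ref: float = 2.0
    E_rest: float = -70.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.C_m <= 0:
            raise ValueError("tau_m and C_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must lie below V_th")

    @property
    def R_m(self) -> float:
        """Membrane resistance in mV/pA (= GOhm)."""
        return self.tau_m / self.C_m


@dataclass(frozen=True)
class ProjectionParams:
    """One projection: alpha-PSC peak (pA, signed), rise time, delay (ms)."""

    peak_amplitude: float
    rise_time: float = 2.0
    delay: float = 1.0
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.rise_time <= 0:
            raise ValueError("rise_time must be positive")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Constant DC current applied to one population over a time window."""

    target_population: str
    amplitude: float            # pA
    t_on: float = 0.0           # ms
    t_off: float = np.inf

    def __post_init__(self) -> None:
        if self.t_on > self.t_off:
            raise ValueError("t_on must not exceed t_off")


def alpha_psc(spike_time: float, t, p: ProjectionParams):
    """Current at time ``t`` due to one spike emitted at ``spike_time``.

    The kernel is zero before the spike arrives (``spike_time + delay``) and
    peaks at ``peak_amplitude`` one rise time after arrival.
    """
    lag = np.asarray(t, dtype=float) - (spike_time + p.delay)
    x = np.clip(lag / p.rise_time, 0.0, None)
    return p.peak_amplitude * np.e * x * np.exp(-x) * (lag >= 0)


def poisson_background(rate: float, duration: float, seed) -> np.ndarray:
    """Homogeneous Poisson spike train: sorted spike times in (0, duration] ms.

    ``rate`` is in spikes/s, ``duration`` in ms.  Reproducible for a fixed
    seed (any entropy acceptable to ``numpy.random.SeedSequence``).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def lif_rate_dc(I_dc: float, p: NeuronParams) -> float:
    """Closed-form stationary firing rate (1/s) under constant current."""
    v_inf = p.E_rest + p.R_m * I_dc
    if v_inf <= p.V_th:
        return 0.0
    isi_ms = p.t_ref + p.tau_m * np.log((v_inf - p.V_reset) / (v_inf - p.V_th))
    return 1000.0 / isi_ms


def _propagators(p: NeuronParams, tau_s: float, dt: float):
    """Exact-integration propagator of the (y1, y2, V) system over one step.

    Returns (P11, P21, P22, P31, P32, PV, P_dc) where PV = exp(-dt/tau_m)
    and P_dc converts a constant current (pA) into its one-step voltage
    increment.
    """
    A = np.array(
        [
            [-1.0 / tau_s, 0.0, 0.0],
            [1.0, -1.0 / tau_s, 0.0],
            [0.0, 1.0 / p.C_m, -1.0 / p.tau_m],
        ]
    )
    P = expm(A * dt)
    PV = float(np.exp(-dt / p.tau_m))
    P_dc = p.R_m * (1.0 - PV)
    return P[0, 0], P[1, 0], P[1, 1], P[2, 0], P[2, 1], PV, P_dc


@dataclass
class _Population:
    name: str
    start: int
    n: int
    params: NeuronParams
    bg_rate: float = 0.0        # spikes/s per neuron
    bg_amplitude: float = 0.0   # pA alpha-PSC peak

    @property
    def sl(self) -> slice:
        return slice(self.start, self.start + self.n)


@dataclass
class _Projection:
    name: str
    pre: _Population
    post: _Population
    W: np.ndarray               # (n_pre, n_post) alpha-PSC peaks, pA
    delay_steps: int
    plastic: bool


class Network:
    """Container for populations and projections; wired before simulation."""

    def __init__(self, rise_time: float = 2.0) -> None:
        self.rise_time = rise_time
        self.populations: dict[str, _Population] = {}
        self.projections: list[_Projection] = []
        self._n = 0

    @property
    def n_neurons(self) -> int:
        return self._n

    def add_population(
        self,
        name: str,
        n: int,
        params: NeuronParams = NeuronParams(),
        bg_rate: float = 0.0,
        bg_amplitude: float = 0.0,
    ) -> _Population:
        if name in self.populations:
            raise ValueError(f"population {name!r} already exists")
        if n < 1:
            raise ValueError("population size must be >= 1")
        pop = _Population(name, self._n, n, params, bg_rate, bg_amplitude)
        self.populations[name] = pop
        self._n += n
        return pop

    def connect(
        self,
        pre: str,
        post: str,
        params: ProjectionParams,
        weights: np.ndarray | None = None,
        name: str | None = None,
    ) -> _Projection:
        """All-to-all projection; ``weights`` overrides the uniform peak."""
        if params.rise_time != self.rise_time:
            raise ValueError(
                "all projections in one network must share the network rise "
                f"time ({self.rise_time} ms); got {params.rise_time}"
            )
        ppre, ppost = self.populations[pre], self.populations[post]
        if weights is None:
            W = np.full((ppre.n, ppost.n), float(params.peak_amplitude))
        else:
            W = np.array(weights, dtype=float)
            if W.shape != (ppre.n, ppost.n):
                raise ValueError("weight matrix shape mismatch")
        proj = _Projection(
            name or f"{pre}->{post}", ppre, ppost, W, 0, params.plastic
        )
        proj._delay_ms = params.delay
        self.projections.append(proj)
        return proj


class Simulation:
    """Stateful clock-driven simulation of a wired :class:`Network`.

    The caller advances the simulation step by step (or in blocks) and may
    register hooks invoked after every step with ``(sim, t_ms, spiked)``
    where ``spiked`` is a boolean array over all neurons.  Hooks implement
    plasticity and environment polling without the engine knowing about
    either.
    """

    BG_CHUNK = 2000  # steps of Poisson background drawn per population batch

    def __init__(self, net: Network, dt: float = 0.1, seed: int = 0) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.net = net
        self.dt = dt
        self.seed = seed
        N = net.n_neurons
        self.t = 0.0
        self.step_index = 0

        # per-neuron parameter and propagator arrays
        self.V = np.empty(N)
        self._Vth = np.empty(N)
        self._Vreset = np.empty(N)
        self._Erest = np.empty(N)
        self._ref_steps = np.empty(N, dtype=np.int64)
        self._P11 = np.empty(N)
        self._P21 = np.empty(N)
        self._P22 = np.empty(N)
        self._P31 = np.empty(N)
        self._P32 = np.empty(N)
        self._PV = np.empty(N)
        self._Pdc = np.empty(N)
        for pop in net.populations.values():
            sl = pop.sl
            P11, P21, P22, P31, P32, PV, Pdc = _propagators(
                pop.params, net.rise_time, dt
            )
            self._P11[sl], self._P21[sl], self._P22[sl] = P11, P21, P22
            self._P31[sl], self._P32[sl] = P31, P32
            self._PV[sl], self._Pdc[sl] = PV, Pdc
            self.V[sl] = pop.params.E_rest
            self._Vth[sl] = pop.params.V_th
            self._Vreset[sl] = pop.params.V_reset
            self._Erest[sl] = pop.params.E_rest
            self._ref_steps[sl] = int(round(pop.params.t_ref / dt))

        self.y1 = np.zeros(N)
        self.y2 = np.zeros(N)
        self._ref = np.zeros(N, dtype=np.int64)
        self.I_dc = np.zeros(N)

        # projection delay steps and ring buffer
        max_delay = 1
        for proj in net.projections:
            steps = int(round(proj._delay_ms / dt))
            if abs(steps * dt - proj._delay_ms) > 1e-9:
                warnings.warn(
                    f"delay {proj._delay_ms} ms of {proj.name} rounded to "
                    f"{steps * dt} ms (integer multiple of dt)"
                )
            proj.delay_steps = max(steps, 1)
            max_delay = max(max_delay, proj.delay_steps)
        self._ring = np.zeros((max_delay + 1, N))
        self._ring_ptr = 0

        # y1 increment per unit peak amplitude: a spike of peak w adds
        # w * e / tau_s to y1' so that y2 peaks at w after tau_s
        self._y1_inc = np.e / net.rise_time

        # background noise: one stream, chunked spike-count cache per population
        self._bg: list[dict] = []
        for pop in net.populations.values():
            if pop.bg_rate > 0.0 and pop.bg_amplitude != 0.0:
                sseq = np.random.SeedSequence(
                    [seed, zlib.crc32(pop.name.encode())]
                )
                self._bg.append(
                    {"pop": pop, "rng": np.random.default_rng(sseq),
                     "cache": None, "pos": 0}
                )

        self.hooks: list = []
        self._spike_times: list[np.ndarray] = []
        self._spike_ids: list[np.ndarray] = []
        self.record_spikes = True

    # ------------------------------------------------------------------
    def population_slice(self, name: str) -> slice:
        return self.net.populations[name].sl

    def set_dc(self, population: str, amplitude: float) -> None:
        """Replace the DC drive of one population (pA per neuron)."""
        self.I_dc[self.population_slice(population)] = amplitude

    def add_dc(self, population: str, amplitude: float) -> None:
        self.I_dc[self.population_slice(population)] += amplitude

    def _background_counts(self) -> np.ndarray | None:
        if not self._bg:
            return None
        inc = np.zeros(self.net.n_neurons)
        for bg in self._bg:
            if bg["cache"] is None or bg["pos"] >= self.BG_CHUNK:
                pop = bg["pop"]
                lam = pop.bg_rate * self.dt / 1000.0
                bg["cache"] = bg["rng"].poisson(lam, size=(self.BG_CHUNK, pop.n))
                bg["pos"] = 0
            counts = bg["cache"][bg["pos"]]
            bg["pos"] += 1
            if counts.any():
                pop = bg["pop"]
                inc[pop.sl] = counts * (pop.bg_amplitude * self._y1_inc)
        return inc

    def step(self) -> np.ndarray:
        """Advance one time step; returns the boolean spike array."""
        net = self.net
        # synaptic arrivals scheduled for this step
        arrivals = self._ring[self._ring_ptr]
        bg = self._background_counts()
        if bg is not None:
            arrivals = arrivals + bg

        # exact propagation of (y1, y2, V)
        y1, y2 = self.y1, self.y2
        newV = (
            self._Erest
            + (self.V - self._Erest) * self._PV
            + self._P31 * y1
            + self._P32 * y2
            + self._Pdc * self.I_dc
        )
        self.y2 = self._P21 * y1 + self._P22 * y2
        self.y1 = y1 * self._P11 + arrivals
        self._ring[self._ring_ptr] = 0.0

        # refractoriness: clamp, then count down
        refractory = self._ref > 0
        newV[refractory] = self._Vreset[refractory]
        self._ref[refractory] -= 1

        spiked = newV >= self._Vth
        spiked &= ~refractory
        if spiked.any():
            newV[spiked] = self._Vreset[spiked]
            self._ref[spiked] = self._ref_steps[spiked]
            # deliver to targets
            for proj in net.projections:
                sl = proj.pre.sl
                pre_spikes = spiked[sl]
                if pre_spikes.any():
                    slot = (self._ring_ptr + proj.delay_steps) % len(self._ring)
                    self._ring[slot, proj.post.sl] += (
                        proj.W[pre_spikes].sum(axis=0) * self._y1_inc
                    )
        self.V = newV
        self._ring_ptr = (self._ring_ptr + 1) % len(self._ring)
        self.t += self.dt
        self.step_index += 1

        if self.record_spikes and spiked.any():
            ids = np.flatnonzero(spiked)
            self._spike_ids.append(ids)
            self._spike_times.append(np.full(ids.size, self.t))
        for hook in self.hooks:
            hook(self, self.t, spiked)
        return spiked

    def advance(self, duration: float) -> None:
        """Run for ``duration`` ms."""
        n = int(round(duration / self.dt))
        for _ in range(n):
            self.step()

    # ------------------------------------------------------------------
    def spike_record(self) -> tuple[np.ndarray, np.ndarray]:
        """All recorded spikes as (neuron_ids, times_ms)."""
        if not self._spike_ids:
            return np.empty(0, dtype=int), np.empty(0)
        return np.concatenate(self._spike_ids), np.concatenate(self._spike_times)

    def clear_spike_record(self) -> None:
        self._spike_ids.clear()
        self._spike_times.clear()

    def population_rate(
        self, name: str, t_start: float, t_stop: float
    ) -> float:
        """Mean per-neuron firing rate (1/s) of a population in a window."""
        ids, times = self.spike_record()
        pop = self.net.populations[name]
        m = (
            (times > t_start)
            & (times <= t_stop)
            & (ids >= pop.start)
            & (ids < pop.start + pop.n)
        )
        dur_s = (t_stop - t_start) / 1000.0
        return float(m.sum()) / (pop.n * dur_s)


def run_network(
    net: Network,
    stimuli: list[StimulusSpec] = (),
    T: float = 1000.0,
    dt: float = 0.1,
    hooks: list = (),
    seed: int = 0,
) -> Simulation:
    """Convenience driver: run a wired network for T ms with DC stimuli.

    Stimulus windows are applied at step resolution.  Returns the finished
    :class:`Simulation`, whose spike record and state can be inspected.
    """
    for s in stimuli:
        if s.target_population not in net.populations:
            raise KeyError(f"unknown population {s.target_population!r}")
    sim = Simulation(net, dt=dt, seed=seed)
    sim.hooks.extend(hooks)
    events: list[tuple[float, str, float]] = []
    for s in stimuli:
        events.append((s.t_on, s.target_population, s.amplitude))
        if np.isfinite(s.t_off):
            events.append((s.t_off, s.target_population, -s.amplitude))
    events.sort(key=lambda e: e[0])
    i = 0
    n_steps = int(round(T / dt))
    for _ in range(n_steps):
        while i < len(events) and events[i][0] <= sim.t + 1e-9:
            sim.add_dc(events[i][1], events[i][2])
            i += 1
        sim.step()
    return sim
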
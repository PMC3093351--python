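"""Stationary rate transfer of the LIF neuron under noisy synaptic input.

Used in three places: calibrating DC amplitudes to population rate targets,
the mean-field model of the critic circuit (phasic-amplitude curve as a
function of the cortico-striatal weight difference), and the mapping of
actor weights to action-selection probabilities.

The diffusion approximation treats the summed synaptic input as Gaussian
white noise with mean ``mu`` and standard deviation ``sigma`` of the free
membrane potential; the stationary rate is then the classical
mean-first-passage-time expression

    nu = [ t_ref + tau_m * sqrt(pi) * int_{y_r}^{y_th} erfcx(-u) du ]^{-1}

with y = (V - mu) / sigma.  The contribution of each input stream to
``sigma`` uses the exact integral of the squared post-synaptic potential of
the alpha-current synapse, so the filtering by the synaptic rise time is
accounted for at the level of the stationary voltage variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx

from .lif import NeuronParams, lif_rate_dc

__all__ = ["InputStream", "membrane_stats", "siegert_rate", "rate_from_inputs"]

_GL_X, _GL_W = np.polynomial.legendre.leggauss(120)


@dataclass(frozen=True)
class InputStream:
    """One stationary Poisson input stream to a neuron.

    ``rate`` is the summed arrival rate in spikes/s (all afferents of this
    stream combined); ``weight`` the alpha-PSC peak per arrival in pA.
    """

    rate: float
    weight: float


def _psp_sq_integral(p: NeuronParams, tau_s: float) -> float:
    """integral of h(t)^2 dt (mV^2 * s) for a unit-peak (1 pA) alpha PSC."""
    # membrane filter of the alpha current, evaluated on a fine grid
    t = np.linspace(0.0, 40.0 * max(tau_s, p.tau_m), 40000)  # ms
    if abs(tau_s - p.tau_m) < 1e-9:
        tau_s = tau_s * (1.0 + 1e-6)
    a, m = 1.0 / tau_s, 1.0 / p.tau_m
    # h(t) = (e / (C_m * tau_s)) * L[t * exp(-a t)](membrane), closed form:
    d = a - m
    h = (
        np.e
        / (p.C_m * tau_s)
        * (
            (np.exp(-m * t) - np.exp(-a * t)) / d**2
            - t * np.exp(-a * t) / d
        )
    )  # mV/ms per pA, times 1000*? -- units resolved below
    # units: current pA through C_m pF gives dV/dt in pA/pF = mV/ms
    val = np.trapezoid(h**2, t)  # (mV)^2 * ms
    return val / 1000.0  # -> mV^2 * s


def membrane_stats(
    p: NeuronParams, I_dc: float, streams: list[InputStream], tau_s: float = 2.0
) -> tuple[float, float]:
    """Mean and std of the free membrane potential (mV) under the inputs."""
    mu = p.E_rest + p.R_m * I_dc
    var = 0.0
    unit_sq = _psp_sq_integral(p, tau_s)
    for s in streams:
        # mean current of an alpha-PSC stream: rate * w * e * tau_s
        mu += p.R_m * s.rate * s.weight * np.e * (tau_s / 1000.0)
        var += s.rate * s.weight**2 * unit_sq
    return mu, float(np.sqrt(var))


def siegert_rate(mu: float, sigma: float, p: NeuronParams) -> float:
    """Stationary firing rate (spikes/s) in the diffusion approximation."""
    if sigma < 1e-9:
        return lif_rate_dc((mu - p.E_rest) / p.R_m, p)
    y_th = (p.V_th - mu) / sigma
    y_r = (p.V_reset - mu) / sigma
    # Gauss-Legendre on [y_r, y_th]
    mid, half = 0.5 * (y_th + y_r), 0.5 * (y_th - y_r)
    u = mid + half * _GL_X
    integral = half * float(np.sum(_GL_W * erfcx(-u)))
    T_ms = p.t_ref + p.tau_m * np.sqrt(np.pi) * integral
    return 1000.0 / T_ms


def rate_from_inputs(
    p: NeuronParams, I_dc: float, streams: list[InputStream], tau_s: float = 2.0
) -> float:
    """Stationary rate of a LIF neuron given DC plus Poisson streams."""
    mu, sigma = membrane_stats(p, I_dc, streams, tau_s)
    return siegert_rate(mu, sigma, p)
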
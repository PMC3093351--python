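"""From synaptic parameters to TD(0) parameters and back.

Fits the linearisation of the critic's phasic-amplitude curve (mean-field
model), maps the plasticity parameters (lambda_v, eta) to the equivalent
discrete-time (alpha, gamma, offset), verifies the closed form against
brute-force integration of the plasticity dynamics over one transition,
and searches the scalar reward equivalent to a reward DC.
"""

import numpy as np

from spiketd.circuit import ArchitectureSpec, CircuitParams
from spiketd.mapping import (
    build_mapping,
    corresponding_reward_search,
    integrate_transition,
    inverse_map,
    map_to_td,
)
from spiketd.plasticity import PlasticityRates

spec = ArchitectureSpec(n_states=2)
pars = CircuitParams()
mp, u, c, _ = build_mapping(spec, pars, dw_range=(-40.0, 40.0))
print(f"linearised amplitude curve: slope u = {u:.4f} Hz/pA, "
      f"intercept c = {c:.3f} Hz")
print(f"value conversion: k = {mp.k:.3f} Hz/pA, m = {mp.m:.4f} V-units/Hz")

rates = inverse_map(alpha=0.1, gamma=0.9, u=u, mp=mp)
alpha, gamma, offset = map_to_td(u, c, rates, mp)
print(f"\ninverse map for (alpha=0.1, gamma=0.9): lambda_v = "
      f"{rates.lambda_v:.3e}, eta = {rates.eta:.4f}")
print(f"forward map recovers alpha = {alpha:.4f}, gamma = {gamma:.4f}, "
      f"offset = {offset:.4f}")

dw = 20.0
wf, wt = 60 - dw / 2, 60 + dw / 2
closed = alpha * (gamma * mp.value_of_weight(wt) - mp.value_of_weight(wf)
                  + offset)
oracle = mp.m * mp.k * integrate_transition(wf, wt, u * dw + c, rates, mp)
print(f"\nper-transition value change at dw = {dw:+.0f} pA: "
      f"closed form {closed:.5f}, numeric integration {oracle:.5f}")

for dc in (60.0, 0.0, -60.0):
    r = corresponding_reward_search(dc, spec, pars, rates)
    print(f"reward DC {dc:+6.1f} pA  ->  discrete reward {r:+.3f}")
print("\nNote the asymmetry: the low tonic rate floor compresses the "
      "negative range.")
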
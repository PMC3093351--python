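"""Closed-loop spiking agent learning a small grid-world.

Runs the full spiking actor-critic (LIF network, first-spike action
selection, dopamine-modulated three-factor plasticity) on a 3x3 grid-world
for a few hundred decisions -- a scaled-down version of the full task that
finishes in about a minute -- and prints the latency decline and the
learned value weights.
"""

import numpy as np

from spiketd.circuit import ArchitectureSpec, CircuitParams
from spiketd.experiments import run_spiking_agent
from spiketd.mapping import build_mapping, inverse_map
from spiketd.plasticity import PlasticityRates
from spiketd.tasks import GridWorld

gw = GridWorld(width=3, height=3, reward_dc_pA=38.0)
spec = ArchitectureSpec(n_states=9)
pars = CircuitParams()

# plasticity rates chosen by the inverse mapping for (alpha, gamma) = (0.1, 0.9)
mp, u0, _, _ = build_mapping(spec, pars, dw_range=(-20.0, 20.0))
inv = inverse_map(0.1, 0.9, u0, mp)
rates = PlasticityRates(lambda_v=inv.lambda_v, lambda_p=inv.lambda_v / 6,
                        eta=inv.eta)

N = 400
res = run_spiking_agent(gw, spec, pars, rates, n_decisions=N, seed=1,
                        warmup=3000.0)
lat = [t.latency for t in res.trials]
n = len(lat)
print(f"{n} trials in {N} decisions; mean latency {np.mean(lat):.1f} steps")
print("\nmean cortico-striatal weight per state (3x3, reward at centre):")
W = res.value_weights.reshape(3, 3)
for y in range(2, -1, -1):
    print("  " + " ".join(f"{W[y, x]:5.1f}" for x in range(3)))

# does the strongest actor weight point towards the reward?
moves = {0: (0, 1), 1: (0, -1), 2: (1, 0), 3: (-1, 0)}  # N S E W
good = 0
for s in range(9):
    if s == gw.reward_state:
        continue
    x, y = s % 3, s // 3
    dx, dy = moves[int(np.argmax(res.actor_weights[s]))]
    before = abs(x - 1) + abs(y - 1)
    after = abs(min(max(x + dx, 0), 2) - 1) + abs(min(max(y + dy, 0), 2) - 1)
    good += after < before
print(f"\npreferred action moves the agent closer to the reward in "
      f"{good}/8 states")
print("\nThe weight map is the value function: highest at the rewarded "
      "centre,\ndecreasing with distance; the actor weights rank the "
      "correct direction\nfirst -- both learned entirely from the "
      "network's own dopaminergic\nerror signal.")
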
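"""Cliff-walk dissection: which biological constraint changes behaviour?

Runs the base discrete-time agent and the modified variants on the
positive-goal cliff-walk and prints where each agent spends its time at
equilibrium.  A bounded TD error (C) or bounded values (D) leave the
strategy unchanged; the self-adapting parameters and offset (F) push the
agent onto the shortest path along the cliff edge; adding value bounds (G)
makes it fall occasionally.
"""

import numpy as np

from spiketd.circuit import ArchitectureSpec, CircuitParams
from spiketd.experiments import (
    equilibrium_histogram,
    make_adaptive_schedule,
    mapped_value_bounds,
    total_variation,
)
from spiketd.tasks import CliffWalk
from spiketd.td import TDParams, VariantConfig

cw = CliffWalk(variant=2)
spec = ArchitectureSpec(n_states=25)
pars = CircuitParams()
vb = mapped_value_bounds(spec, pars)

variants = {
    "base": VariantConfig(),
    "C (bounded error)": VariantConfig(delta_min=-0.464),
    "D (bounded values)": VariantConfig(v_bounds=vb),
    "F (self-adapting)": VariantConfig(
        adaptive=make_adaptive_schedule(cw, spec, pars)),
    "G (F + bounded values)": VariantConfig(
        adaptive=make_adaptive_schedule(cw, spec, pars), v_bounds=vb),
}

ns = [s for s in range(25) if s not in cw.special_states]
row1 = [s for s in ns if 5 <= s < 10]
base_h = None
for name, vc in variants.items():
    h, _ = equilibrium_histogram(cw, TDParams(), vc, seed=0)
    if base_h is None:
        base_h = h
    print(f"{name:24s} cliff-row share {h[row1].sum() / h[ns].sum():5.1%}  "
          f"cliff entries {h[list(cw.cliff)].sum():4.1f}%  "
          f"TV vs base {total_variation(h, base_h):.3f}")
print("\nShares are visits to the cliff-adjacent row among ordinary states;"
      "\nTV is the total-variation distance between visit histograms.")
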
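"""Dopaminergic error signal of the critic circuit.

Builds the two-state critic circuit, checks that the tonic dopamine rate is
independent of the learned cortico-striatal weights (the baseline
condition), and sweeps the phasic amplitude as a function of the weight
difference of a forced transition, with and without a reward DC.

The amplitude plays the role of the reward-prediction error: positive when
the agent moves to a higher-valued state, negative (but floored at minus
the tonic rate) when it moves to a lower-valued one, and offset upward when
an external reward is delivered.
"""

import numpy as np

from spiketd.circuit import (
    ArchitectureSpec,
    CircuitParams,
    measure_phasic_amplitude,
    verify_baseline,
)

spec = ArchitectureSpec(n_states=2)
params = CircuitParams()

report = verify_baseline(spec, params, np.linspace(20, 100, 3), seed=0,
                         window=3000.0)
print("tonic DA rate vs clamped weight:")
for w, r in zip(report["weights"], report["rates"]):
    print(f"  w = {w:5.1f} pA -> {r:4.2f} spikes/s")
print(f"max relative deviation: {report['max_rel_deviation']:.1%} "
      f"(baseline condition {'holds' if report['passed'] else 'violated'})")

print("\nphasic amplitude vs weight difference (10 trials/point):")
for dw, (wf, wt) in [(-80, (100, 20)), (0, (60, 60)), (80, (20, 100))]:
    m0 = measure_phasic_amplitude(spec, params, wf, wt, n_trials=10, seed=1)
    m1 = measure_phasic_amplitude(spec, params, wf, wt, reward_dc=60.0,
                                  n_trials=10, seed=1)
    print(f"  dw = {dw:+4d} pA: {m0.amplitude:+6.2f} Hz unrewarded, "
          f"{m1.amplitude:+6.2f} Hz with reward DC")
print("\nA positive weight difference raises the dopamine rate above its "
      "baseline;\na strongly negative one can at most silence the neurons "
      "(the asymmetry\nthat ultimately breaks learning from punishments).")
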
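# spiketd

Spiking actor-critic temporal-difference learning driven by a
network-generated dopaminergic error signal.

## What this package is for

A long-standing question in systems neuroscience is how dopamine-modulated
synaptic plasticity in the basal ganglia could implement
temporal-difference (TD) learning, given that the phasic activity of
midbrain dopamine neurons only imperfectly resembles the theoretical TD
error: the tonic rate is low, so negative errors have a small dynamic
range; the response is a nonlinear function of the underlying value
difference; and its slope changes when an external reward is present.
`spiketd` implements, in one package:

* a **spiking actor-critic agent**: current-based leaky integrate-and-fire
  neurons with alpha-shaped post-synaptic currents; cortical pools encoding
  task states; a critic circuit (striatum -> ventral pallidum -> dopamine
  neurons, plus a delayed direct striatum -> dopamine pathway, all
  inhibitory) whose phasic population-rate excursion is the agent's
  reward-prediction error; one actor neuron per action read out by the
  first spike;
* two **three-factor plasticity rules** in which a pre-synaptic activity
  trace, a pre-synaptic efficacy trace (and, for the policy synapses, a
  post-synaptic trace) gate a weight change proportional to the deviation
  of the global dopamine concentration from its baseline:

      cortex->striatum :  dw/dt = lambda_v * A_pre * E_pre * (D - b - eta * A_post)
      cortex->actor    :  dw/dt = lambda_p * A_pre * E_pre * A_post * (D - b)

* the **classical discrete-time TD(0) actor-critic** (Gibbs-softmax policy
  over bounded preferences, `delta = r + gamma V(s') - V(s)`) and a family
  of modified variants that add, one at a time, the biological constraints
  of the spiking system (bounded error, bounded values, discount only in
  the value update, self-adapting learning rate / discount / offset);
* the **grid-world** and **cliff-walk** benchmark tasks (continuing tasks,
  5x5 lattice, teleporting cliff and goal states, both all-negative and
  positive-goal reward schedules);
* the **analytical parameter mapping** between the synaptic quantities
  (lambda_v, eta, weight units) and the algorithmic ones (alpha, gamma,
  offset, value units), obtained by integrating the plasticity dynamics
  over one idealised transition and linearising the dopaminergic amplitude
  curve piecewise, together with a brute-force integration oracle, the
  inverse mapping, and a search for the scalar reward equivalent to a
  reward DC.

## A worked example

```sh
python examples/04_parameter_mapping.py
```

prints, for the default circuit:

```
linearised amplitude curve: slope u = 0.2315 Hz/pA, intercept c = 2.169 Hz
value conversion: k = 0.664 Hz/pA, m = 0.0377 V-units/Hz

inverse map for (alpha=0.1, gamma=0.9): lambda_v = 3.099e-03, eta = 0.0267
forward map recovers alpha = 0.1000, gamma = 0.9000, offset = 0.0925

per-transition value change at dw = +20 pA: closed form 0.05675, numeric integration 0.05675
reward DC  +60.0 pA  ->  discrete reward +1.699
reward DC   +0.0 pA  ->  discrete reward -0.000
reward DC  -60.0 pA  ->  discrete reward -0.451
```

Reading this: the critic's phasic amplitude rises by about 0.23 Hz per pA
of cortico-striatal weight difference; a desired discount factor of 0.9 is
realised by the post-trace coefficient eta = 0.027; the closed-form value
update matches the numerical integration of the synaptic dynamics; and the
floor of the dopaminergic signal compresses punishments (a -60 pA DC maps
to only -0.45 value units while +60 pA maps to +1.7) -- the asymmetry that
lets the agent learn from sparse positive rewards but not from purely
negative ones.

The other examples cover the dopaminergic signal properties
(`01_dopaminergic_signal.py`), discrete grid-world learning
(`02_td_gridworld.py`, latency falls below one step and the value table
forms a gradient towards the reward), the cliff-walk variant dissection
(`03_cliffwalk_variants.py`) and a closed-loop spiking grid-world run
(`05_spiking_gridworld.py`).  `spiketd.experiments.experiment_driver`
writes the whole scaled-down suite as CSV artifacts.

## Layout

```
src/spiketd/
  lif.py          clock-driven LIF engine (exact integration, delays, noise)
  plasticity.py   traces, dopamine field, three-factor rules
  circuit.py      the actor-critic architecture, calibration, measurements
  tasks.py        grid-world and cliff-walk environments and metrics
  td.py           discrete-time TD(0) agent and modified variants
  mapping.py      synaptic <-> algorithmic parameter mapping + oracle
  transfer.py     LIF rate-transfer functions (f-I curve, diffusion approx.)
  experiments.py  closed-loop spiking runs, mapped variants, driver
```

See `docs/methods.md` for the model description, parameter choices and
known limitations.
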
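# Methods

## Model overview

All neurons are current-based leaky integrate-and-fire (LIF) units,

    tau_m dV/dt = -(V - E_rest) + R_m I(t),

with threshold V_th, reset V_reset and absolute refractory period t_ref;
every spike arriving over a projection injects an alpha-shaped
post-synaptic current peaking at the projection's weight (pA) one rise
time after arrival.  The engine advances the coupled (current, voltage)
system with the exact matrix-exponential propagator at a fixed step
(default dt = 0.1 ms); threshold crossings are detected at step
boundaries; transmission delays are ring buffers in units of dt
(non-commensurate delays are rounded with a warning).  All projections of
one network share a single synaptic rise time — the per-channel state the
engine keeps is per neuron, not per projection — which is the only
restriction relative to fully heterogeneous synapses.  Poisson background
noise is delivered as spike trains through a per-population background
projection; each population draws from an independent stream derived from
the master seed and the population name, so resizing one population never
reshuffles another's noise (per-neuron streams would be the ideal; they
are prohibitively slow in a vectorised implementation, and the
per-population scheme preserves the property that matters).

### The critic circuit

Each task state is a cortical pool; the environment drives the pool of the
occupied state with a DC current.  The cortex projects through plastic
synapses to a striatal population (the value readout: the mean
cortico-striatal weight of a state encodes its value) and to one actor
neuron per action.  The striatum inhibits a ventral-pallidum population,
which inhibits the dopamine neurons (fast, net-excitatory "indirect"
pathway), and also inhibits the dopamine neurons directly with a long
delay ("direct" pathway).  In the stationary state the two pathways
cancel whenever (i) the VP relays striatal rate changes with a gain of -1
and (ii) the STR->DA and VP->DA weights are equal in magnitude; the tonic
dopamine rate is then independent of the learned weights (the baseline
condition).  For `d_direct - d_indirect` = 100 ms after a state
transition the direct pathway still reports the previous state's striatal
rate while the indirect one already reports the new state's, producing a
phasic rate excursion — the network's reward-prediction error.  External
rewards are DC currents injected into the dopamine population during the
phasic window (onset one indirect delay after the move).

Action selection is a first-spike race between the actor neurons;
afterwards the environment inhibits all actor neurons for `t_inhib` =
150 ms with a negative DC while the new state's cortical signal builds
up.  Simultaneous first spikes within one step are broken uniformly at
random from the run's own stream.  Because the inhibition synchronises
the actor membranes, the weight-to-probability readout models the race
as a first-passage problem: each actor's potential is an
Ornstein-Uhlenbeck process (diffusion approximation of its cortical
drive) started at the inhibited level, and the first to cross threshold
wins -- considerably sharper than a memoryless rate-ratio race, and
validated against the full spiking readout.

### Plasticity

Each plastic synapse keeps a pre-synaptic activity trace A (incremented by
1000/tau_pre per spike, decaying with tau_pre, so its stationary mean is
the firing rate in spikes/s) and a pre-synaptic efficacy trace E (reset to
0 at each pre spike, relaxing to 1 with tau_e >> tau_pre).  The product
A*E is small while the pre-synaptic neuron fires steadily and transiently
large just after it stops — confining weight changes mainly to the period
after the agent exits a state, when the phasic dopamine signal carries
that transition's error.  (The confinement is imperfect: for Poisson
firing, the ratio of the within-dwell product to the post-exit peak is set
by rate x tau_pre and cannot be made arbitrarily small while the activity
trace still decays within one dwell.  Within-dwell sensitivity couples to
zero-mean baseline fluctuations and contributes drift, not bias.)

The dopamine concentration D is a global scalar: each dopaminergic spike
increments it by one and it decays with the striatal uptake time
tau_DA = 100 ms; the baseline b is measured once during a stimulus-free
warm-up (default 5 s) and kept fixed.  Weight updates are applied every
time step (Euler) and hard-clipped to their bounds:

    cortex->striatum : dw/dt = lambda_v A E (D - b - eta A_post),
    cortex->actor    : dw/dt = lambda_p A E A_act (D - b),

where A_post is the striatal neuron's activity trace (it converts the
amplitude's dependence on the *total* new-state value into a discounted
one; eta = 0 recovers the undiscounted rule) and A_act flags the most
recently chosen action.

## Parameter mapping

Integrating the cortico-striatal rule over one idealised transition
(pre-pool active at r_a until exit, then silent; phasic excursion of
amplitude a over the delay window, filtered by tau_DA; striatal trace
relaxing from the old to the new state's rate) gives a closed form in
three constants K_D, K_1, K_2 that depend only on time constants and
circuit timing.  With the amplitude linearised as a = u*dw + c over a
weight-difference range, and values identified with striatal rates
(V = m*k*(w - w_init): equal initial weights mean zero initial values),
the per-transition value change is alpha (gamma V' - V + o) with

    alpha = lambda_v (u K_D + eta k K_2)
    gamma = (u K_D - eta k (K_1 - K_2)) / (u K_D + eta k K_2)
    o     = m k (c K_D - eta K_1 rho(w_init)) / (u K_D + eta k K_2).

eta = 0 gives gamma = 1 exactly; lambda_v scales alpha only; all (alpha,
gamma) combinations are reachable independently.  Because u and c depend
on the weight-difference range and on the reward DC, the equivalent
algorithm has self-adapting parameters; the adaptive discrete variants
linearise the curve over five segments per reward class and look the
segment up per transition.  The amplitude curve used by the mapping layer
comes from a deterministic mean-field model of the critic (stationary LIF
rates in the diffusion approximation, with the exact squared-PSP integral
entering the voltage variance); the spiking measurement of the same curve
is kept as a separate, stochastic route so the two never collapse into
one.

One constant is not derivable from this package's circuit: the
self-adapting variants carry a per-transition offset on unrewarded moves
that acts like a small negative step reward and drives the adaptive agent
onto the shortest, cliff-adjacent path.  The mean-field intercept alone
gives only about -0.09 value units; the documented strategy requires about
-0.3, which is the value fixed in `AdaptiveMapping.TRANSITION_OFFSET`
(probes show the edge-walking pattern appears for offsets of -0.3 and
stronger and is absent at -0.1).  The adaptive variants also express each
class's update in nominal-step units before applying the optional error
bound, which both scales the actor update in the same proportion as the
critic's and makes the bound modification orthogonal to the adaptive one.

## Default parameters

LIF: tau_m 10 ms, C_m 250 pF, V_th -55 mV, V_reset = E_rest = -70 mV,
t_ref 2 ms; rise time 2 ms; background 800 spikes/s at 57.5 pA per neuron
(free membrane mean -60 mV, sd ~2.2 mV).  Populations (reduced scale): 10
cortical neurons per state, 20 each in striatum, VP and DA, one actor
neuron per action.  Delays: indirect path 5 + 5 ms, direct 110 ms (phasic
duration 100 ms, matching the experimentally observed order).  Active
cortical pools are driven to 40 spikes/s; unstimulated pools sit at ~2
spikes/s; VP at ~50 spikes/s; tonic DA at ~4.5 spikes/s (the
experimentally observed low tonic rate).  Cortico-striatal and
cortex-actor weights live in [20, 100] pA, initialised at 60.  Traces:
tau_pre 50 ms, tau_e 500 ms, striatal and actor post traces 100 ms.  The
operating-point DCs and the STR->VP weight are set by
`spiketd.circuit.calibrate`, which adjusts them empirically (short
simulations) to the rate targets, the VP gain of -1 and, directly, to the
invariance of the tonic DA rate across clamped weight settings; the
shipped defaults are the calibration result for the two-state circuit.

Discrete agents: alpha = beta = 0.1, gamma = 0.9; preference bounds of
width ln 27, so a saturated state picks its preferred action with
probability 0.9 (and any action with at least ~0.033 — the residual
exploration).  Grid-world: 5x5, reward +1 at the centre, uniformly random
restarts.  Cliff-walk: start lower-left, goal lower-right, three cliff
states between them; entering cliff or goal teleports to the start on the
following move.  Variant 1 (all-negative): -1 for the cliff, -0.5 for
every ordinary move *including wall bumps* (only goal arrival and the
teleport return are free — charging bumps is what makes idling strictly
worse than running the cliff edge, the behaviour the task is designed to
elicit); variant 2: +1 at the goal and -0.45 for the cliff, the scale
regenerated from the mapping (the goal DC is chosen so the mapped reward
is exactly one unit; a -60 pA cliff DC maps to -0.45 because the tonic
floor compresses punishments).

## Problem sizes used in the shipped experiments

The spiking measurements run on a two-state circuit (~120 neurons):
baseline invariance over four clamped weight settings with 8 s windows;
amplitude curves over five weight differences x 25 forced transitions per
point.  Spiking learning runs use a 3x3 grid-world (400 decisions) and
the 25-state cliff-walk (500 decisions) — scaled-down versions of the
full-length tasks, chosen so the whole suite completes on one CPU in
minutes; at that scale learning trends and the value-floor collapse are
clearly resolved, while full learning curves to equilibrium would need
runs of hours of biological time.  Discrete-agent experiments use
20,000–60,000 action selections and 8–16 seeds.

## What the scaled runs do and do not show

The desk-scale spiking runs demonstrate the mechanisms — tonic-rate
invariance, the monotone/floored/reward-steepened amplitude curve,
latency decline on the small grid-world, and the collapse of all value
weights to their floor on the all-negative cliff-walk — but not the full
quantitative learning curves of the large tasks.  The synthetic
environments are deterministic lattices with teleports; they contain no
perceptual noise, no overlapping state representations and no spatial
generalisation, so conclusions transfer to real behavioural data only at
the level of the algorithmic constraints studied here.

## Numerical choices and degenerate inputs

Exact integration makes the engine stable for any dt dividing the delays;
halving dt changes rates by well under 1%.  The diffusion-approximation
rate transfer is accurate to ~10–20% at the operating points used; all
quantities that matter are therefore calibrated empirically against the
spiking network rather than taken from the approximation.  The mapping
refuses weight differences outside its fitted range (adaptive schedules
clamp and count them); `fit_linearization` can enforce a residual bound;
the first-spike readout raises after a configurable timeout if no actor
neuron fires (pathological weights).  Ties in the actor race within one
step are broken uniformly at random.

## Known limitations

* Negative rewards are structurally under-represented (by design — that
  is the phenomenon under study): the mapped punishment scale saturates
  near half a value unit regardless of the DC amplitude.
* The unrewarded-class transition offset of the adaptive variants is a
  reconstructed constant, not derived from this circuit's amplitude curve
  (see above).
* The equilibrium latency of the discrete agent on the positive-goal
  cliff-walk depends almost entirely on the residual-exploration floor of
  the bounded softmax; with the 0.9/0.033 probability caps it comes out
  near 3.4 steps, at the upper edge of "approximately 3".
* In closed-loop spiking runs the actor weights drift towards their upper
  bound (most moves along a learned value gradient produce a positive
  error, so most chosen actions are reinforced); the bound prevents the
  runaway that would otherwise destroy learning, at the price of
  compressed differentiation between actions once saturated.  At desk
  scale the learned policy is visible as the *ranking* of the actor
  weights (the correct direction comes first) rather than as a large
  probability margin.
* Conductance-based synapses, receptor kinetics, sparse connectivity and
  biologically grounded action-selection circuits are all out of scope;
  connectivity is all-to-all with uniform weights.
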
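"""Discrete-time actor-critic TD(0) reference agent and modified variants.

The classical algorithm maintains a tabular value function V(s) and action
preferences h(s, a).  On each move s -> s' with reward r it computes the TD
error

    delta = r + gamma * V(s') - V(s)

and updates only the most recently exited state and the chosen action:

    V(s)    += alpha * delta
    h(s, a) += beta  * delta

Actions are drawn from the Gibbs softmax distribution over the preferences
of the current state.  Preferences are hard-bounded, mirroring the synaptic
weight bounds of the spiking agent and guaranteeing residual exploration.

The variant switches reproduce, one biological constraint at a time, the
deviations of the spiking network from the classical algorithm:

* ``delta_min``        -- lower bound on the TD error (limited dynamic range
                          of the dopaminergic rate below its baseline);
* ``v_bounds``         -- hard bounds on the value function (synaptic weight
                          bounds on the cortico-striatal projection);
* ``policy_discount``  -- when False, the policy update uses the undiscounted
                          error r + V(s') - V(s) (the dopamine signal carries
                          no discount for the actor synapses);
* ``adaptive``         -- self-adapting effective learning rate, discount and
                          offset derived from the nonlinear dopaminergic
                          amplitude curve (supplied by the mapping layer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .tasks import RewardEvent, TrialRecord

__all__ = [
    "TDParams",
    "VariantConfig",
    "ValuePolicyTables",
    "AgentRun",
    "td_error",
    "softmax_policy",
    "update_tables",
    "run_agent",
]


# Preference bounds chosen so that a fully saturated state (one preference at
# the upper bound, the rest at the lower) selects its preferred action with
# probability 0.9: h_max - h_min = ln(3 * 0.9 / 0.1) = ln 27.
H_MAX_DEFAULT = float(np.log(27.0))


@dataclass(frozen=True)
class TDParams:
    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 0.9
    h_min: float = 0.0
    h_max: float = H_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("step sizes must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.h_min > self.h_max:
            raise ValueError("h_min must not exceed h_max")


class AdaptiveSchedule(Protocol):
    """Per-transition effective parameters of the equivalent TD algorithm.

    Given the reward event of the current transition and the value estimates
    of the exited and entered states, return ``(alpha_eff, gamma_eff,
    offset)``.  The TD error then becomes ``gamma_eff * V(s') - V(s) +
    offset``: the external reward enters only through the offset, exactly as
    it enters the dopaminergic amplitude curve through the reward DC.
    """

    def __call__(
        self, event: RewardEvent, v_prev: float, v_next: float
    ) -> tuple[float, float, float]: ...


@dataclass(frozen=True)
class VariantConfig:
    delta_min: float | None = None
    v_bounds: tuple[float, float] | None = None
    policy_discount: bool = True
    adaptive: AdaptiveSchedule | None = None

    def __post_init__(self) -> None:
        if self.v_bounds is not None and self.v_bounds[0] > self.v_bounds[1]:
            raise ValueError("v_bounds must be ordered (min, max)")


BASE = VariantConfig()


@dataclass
class ValuePolicyTables:
    V: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, n_states: int, n_actions: int, v0: float = 0.0, h0: float = 0.0):
        return cls(
            V=np.full(n_states, float(v0)),
            h=np.full((n_states, n_actions), float(h0)),
        )


def td_error(
    r: float,
    v_next: float,
    v_prev: float,
    gamma: float,
    delta_min: float | None = None,
) -> float:
    delta = r + gamma * v_next - v_prev
    if delta_min is not None and delta < delta_min:
        delta = delta_min
    return delta


def softmax_policy(h_row: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Gibbs softmax distribution over the preferences of one state."""
    z = np.asarray(h_row, dtype=float) / temperature
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def update_tables(
    tables: ValuePolicyTables,
    s_prev: int,
    a_prev: int,
    delta_value: float,
    delta_policy: float,
    params: TDParams,
    variant: VariantConfig = BASE,
    alpha_override: float | None = None,
) -> ValuePolicyTables:
    """Apply one TD update in place.

    Only ``V(s_prev)`` and ``h(s_prev, a_prev)`` change.  ``alpha_override``
    carries the self-adapting learning rate of the adaptive variants.
    """
    alpha = params.alpha if alpha_override is None else alpha_override
    tables.V[s_prev] += alpha * delta_value
    if variant.v_bounds is not None:
        lo, hi = variant.v_bounds
        tables.V[s_prev] = min(max(tables.V[s_prev], lo), hi)
    tables.h[s_prev, a_prev] = min(
        max(tables.h[s_prev, a_prev] + params.beta * delta_policy, params.h_min),
        params.h_max,
    )
    return tables


@dataclass
class AgentRun:
    states: np.ndarray          # state occupied before each move
    actions: np.ndarray
    rewards: np.ndarray         # scalar reward received on each move
    entered: np.ndarray         # state entered by each move
    trials: list[TrialRecord]
    tables: ValuePolicyTables
    goal_arrivals: int
    falls: int


def run_agent(
    task,
    params: TDParams = TDParams(),
    variant: VariantConfig = BASE,
    n_steps: int = 10_000,
    seed: int = 0,
    v0: float = 0.0,
    h0: float = 0.0,
) -> AgentRun:
    """Run the (possibly modified) discrete-time actor-critic for n_steps.

    Action sampling and environment randomness (restart positions) use two
    independent streams derived from ``seed``, so that policy changes do not
    perturb the restart sequence.  The task is continuing: learning updates
    are applied on every move, including teleport moves out of terminal
    states, but trial statistics only cover the span from a placement to the
    next arrival at the task's target state.
    """
    ss = np.random.SeedSequence(seed)
    policy_rng, env_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    tables = ValuePolicyTables.zeros(task.n_states, task.n_actions, v0, h0)
    s = task.initial_state(env_rng)

    states = np.empty(n_steps, dtype=np.int64)
    actions = np.empty(n_steps, dtype=np.int64)
    rewards = np.empty(n_steps, dtype=float)
    entered = np.empty(n_steps, dtype=np.int64)
    trials: list[TrialRecord] = []
    goal_arrivals = 0
    falls = 0

    in_trial = not task.is_trial_end(s)
    trial_start, trial_steps, trial_reward, trial_falls = s, 0, 0.0, 0
    if not in_trial:  # placed directly on the target state
        trials.append(TrialRecord(s, 0, 0, 0.0, 0))

    for t in range(n_steps):
        p = softmax_policy(tables.h[s])
        a = int(policy_rng.choice(task.n_actions, p=p))
        nxt, event = task.transition(s, a, env_rng)

        v_prev = float(tables.V[s])
        v_next = float(tables.V[nxt])
        alpha_override = None
        if variant.adaptive is not None:
            alpha_eff, gamma_eff, offset = variant.adaptive(
                event, v_prev, v_next
            )
            # express the self-adapting update in nominal-step units, so
            # the optional delta bound compares like with like and the
            # flattened amplitude curve attenuates critic and actor
            # updates in the same proportion
            delta = (alpha_eff / params.alpha) * (
                gamma_eff * v_next - v_prev + offset
            )
            if variant.delta_min is not None and delta < variant.delta_min:
                delta = variant.delta_min
            delta_policy = delta
        else:
            delta = td_error(event.value, v_next, v_prev, params.gamma,
                             variant.delta_min)
            delta_policy = delta if variant.policy_discount else td_error(
                event.value, v_next, v_prev, 1.0, variant.delta_min
            )
        update_tables(tables, s, a, delta, delta_policy, params, variant,
                      alpha_override)

        states[t], actions[t], rewards[t], entered[t] = s, a, event.value, nxt
        if event.kind == "cliff":
            falls += 1
            if in_trial:
                trial_falls += 1
        if event.kind == "goal":
            goal_arrivals += 1

        if in_trial:
            trial_steps += 1
            trial_reward += event.value
            if task.is_trial_end(nxt):
                trials.append(
                    TrialRecord(
                        start_state=trial_start,
                        steps=trial_steps,
                        latency=trial_steps - task.min_steps(trial_start),
                        total_reward=trial_reward,
                        falls=trial_falls,
                    )
                )
                in_trial = False
        else:
            # the move out of a terminal state places the agent; it does not
            # count towards any trial
            trial_start, trial_steps, trial_reward, trial_falls = nxt, 0, 0.0, 0
            if task.is_trial_end(nxt):
                trials.append(TrialRecord(nxt, 0, 0, 0.0, 0))
            else:
                in_trial = True
        s = nxt

    return AgentRun(states, actions, rewards, entered, trials, tables,
                    goal_arrivals, falls)
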
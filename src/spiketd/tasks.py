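"""Discrete-state benchmark tasks: grid-world and cliff-walk.

Both tasks live on a rectangular lattice whose states are indexed row-major
from the lower-left corner, ``state = y * width + x``.  Actions are the four
compass directions; a move that would leave the lattice leaves the position
unchanged.  The environments are agent-agnostic: the same transition function
serves the discrete-time TD(0) agents and the spiking network agent (which
receives rewards as DC-current amplitudes rather than scalars).

Grid-world: a single rewarded state on a 5x5 lattice.  After the agent finds
the reward and selects one further action it is teleported to a uniformly
random restart state, making this a continuing task with no terminal states.

Cliff-walk: 5x5 lattice with a start state in the lower-left corner, a goal
state in the lower-right corner and three cliff states in between.  Entering
a cliff state or the goal sends the agent back to the start on its next move.
Variant 1 is driven purely by negative rewards (large for the cliff, small
for every ordinary state); variant 2 by a positive goal reward and a negative
cliff reward.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

# Actions, fixed order used by all agents.
NORTH, SOUTH, EAST, WEST = 0, 1, 2, 3
ACTION_NAMES = ("north", "south", "east", "west")
_MOVES = {NORTH: (0, 1), SOUTH: (0, -1), EAST: (1, 0), WEST: (-1, 0)}


@dataclass(frozen=True)
class RewardEvent:
    """Reward delivered on entering a state.

    ``value`` is the scalar reward seen by discrete-time agents; ``dc_pA`` is
    the equivalent DC-current amplitude injected into the dopaminergic
    population of the spiking agent.  ``kind`` classifies the entered state
    (``"goal"``, ``"cliff"`` or ``"other"``) for reward-class dependent
    parameter lookups.
    """

    value: float
    dc_pA: float
    kind: str = "other"


@dataclass
class TrialRecord:
    start_state: int
    steps: int
    latency: int
    total_reward: float
    falls: int = 0


class _LatticeTask:
    """Shared lattice geometry and shortest-path machinery."""

    width: int = 5
    height: int = 5
    n_actions: int = 4

    def __init__(self) -> None:
        self._min_steps: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.width * self.height

    def coords(self, state: int) -> tuple[int, int]:
        return state % self.width, state // self.width

    def state_at(self, x: int, y: int) -> int:
        return y * self.width + x

    def _move(self, state: int, action: int) -> int:
        x, y = self.coords(state)
        dx, dy = _MOVES[action]
        nx, ny = x + dx, y + dy
        if 0 <= nx < self.width and 0 <= ny < self.height:
            return self.state_at(nx, ny)
        return state  # off-grid move: position unchanged

    # -- shortest paths (breadth-first search on the actual dynamics) ------
    def min_steps(self, start: int) -> int:
        """Minimum number of moves from ``start`` to the target state."""
        if self._min_steps is None:
            self._min_steps = self._bfs_distances()
        d = self._min_steps[start]
        if d < 0:
            raise ValueError(f"target unreachable from state {start}")
        return int(d)

    def _bfs_distances(self) -> np.ndarray:
        target = self.target_state
        dist = np.full(self.n_states, -1, dtype=int)
        dist[target] = 0
        queue: deque[int] = deque([target])
        # BFS on the reversed transition graph of the deterministic moves.
        preds: dict[int, set[int]] = {s: set() for s in range(self.n_states)}
        for s in range(self.n_states):
            if self._absorbing(s):
                continue
            for a in range(self.n_actions):
                preds[self._move(s, a)].add(s)
        while queue:
            s = queue.popleft()
            for p in preds[s]:
                if dist[p] < 0:
                    dist[p] = dist[s] + 1
                    queue.append(p)
        return dist

    def _absorbing(self, state: int) -> bool:
        """States whose next move is a teleport rather than a lattice move."""
        return False

    # subclasses define: target_state, transition, initial_state


class GridWorld(_LatticeTask):
    """Continuing grid-world with one rewarded state and random restarts."""

    def __init__(
        self,
        width: int = 5,
        height: int = 5,
        reward_state: int | None = None,
        reward_value: float = 1.0,
        reward_dc_pA: float = 200.0,
    ) -> None:
        super().__init__()
        self.width = width
        self.height = height
        # default reward position: centre of the lattice
        if reward_state is None:
            reward_state = self.state_at(width // 2, height // 2)
        self.reward_state = reward_state
        self.reward_value = reward_value
        self.reward_dc_pA = reward_dc_pA

    @property
    def target_state(self) -> int:
        return self.reward_state

    def initial_state(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.n_states))

    def transition(
        self, state: int, action: int, rng: np.random.Generator
    ) -> tuple[int, RewardEvent]:
        if state == self.reward_state:
            # The move following the rewarded state teleports the agent to a
            # uniformly random restart, independent of the chosen action.
            nxt = int(rng.integers(self.n_states))
            return nxt, self._event(nxt)
        nxt = self._move(state, action)
        return nxt, self._event(nxt)

    def _event(self, entered: int) -> RewardEvent:
        if entered == self.reward_state:
            return RewardEvent(self.reward_value, self.reward_dc_pA, "goal")
        return RewardEvent(0.0, 0.0, "other")

    def is_trial_end(self, entered: int) -> bool:
        return entered == self.reward_state


class CliffWalk(_LatticeTask):
    """Cliff-walk task, variants 1 (all-negative) and 2 (positive goal).

    Start in the lower-left corner, goal in the lower-right, three cliff
    states in between.  Entering a cliff state or the goal teleports the
    agent back to the start on the following move.  A trial ends only when
    the goal is reached, regardless of how often the agent falls.
    """

    def __init__(
        self,
        variant: int = 2,
        r_goal: float = 1.0,
        r_cliff: float | None = None,
        r_step: float = -0.5,
        dc_goal_pA: float = 38.0,
        dc_cliff_pA: float = -60.0,
        dc_step_pA: float = -20.0,
    ) -> None:
        super().__init__()
        if variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        self.variant = variant
        if r_cliff is None:
            # variant 2 uses the scale mapped from the DC amplitudes (unit
            # goal reward, floor-compressed cliff penalty); variant 1 keeps
            # the conventional scalar penalties
            r_cliff = -0.45 if variant == 2 else -1.0
        self.start = self.state_at(0, 0)
        self.goal = self.state_at(self.width - 1, 0)
        self.cliff = frozenset(self.state_at(x, 0) for x in range(1, self.width - 1))
        self.r_goal = r_goal
        self.r_cliff = r_cliff
        self.r_step = r_step
        self.dc_goal_pA = dc_goal_pA
        self.dc_cliff_pA = dc_cliff_pA
        self.dc_step_pA = dc_step_pA

    @property
    def target_state(self) -> int:
        return self.goal

    @property
    def special_states(self) -> frozenset[int]:
        return self.cliff | {self.start, self.goal}

    def _absorbing(self, state: int) -> bool:
        return state == self.goal or state in self.cliff

    def initial_state(self, rng: np.random.Generator) -> int:
        return self.start

    def transition(
        self, state: int, action: int, rng: np.random.Generator
    ) -> tuple[int, RewardEvent]:
        if self._absorbing(state):
            # sent back to the start regardless of the selected action; the
            # teleport itself carries no reward
            return self.start, RewardEvent(0.0, 0.0, "other")
        nxt = self._move(state, action)
        return nxt, self._event(nxt)

    def _event(self, entered: int) -> RewardEvent:
        """Reward for arriving at ``entered`` by an ordinary move.

        In variant 1 every ordinary move is charged the per-step penalty --
        including moves that bump a wall and re-enter the current state --
        except arrival at the goal, which is free.  Charging wall bumps is
        what makes idling strictly worse than running the cliff edge to the
        goal, the behaviour the all-negative task is designed to elicit.
        """
        if entered in self.cliff:
            return RewardEvent(self.r_cliff, self.dc_cliff_pA, "cliff")
        if entered == self.goal:
            if self.variant == 2:
                return RewardEvent(self.r_goal, self.dc_goal_pA, "goal")
            return RewardEvent(0.0, 0.0, "goal")
        if self.variant == 1:
            return RewardEvent(self.r_step, self.dc_step_pA, "other")
        return RewardEvent(0.0, 0.0, "other")

    def is_trial_end(self, entered: int) -> bool:
        return entered == self.goal


def latency(record: TrialRecord) -> int:
    """Steps taken in excess of the shortest path; non-negative."""
    if record.latency < 0:
        raise ValueError("negative latency: record is inconsistent")
    return record.latency


def visit_histogram(states: np.ndarray, n_states: int) -> np.ndarray:
    """Per-state visit frequencies as percentages (summing to 100)."""
    states = np.asarray(states, dtype=int)
    if states.size == 0:
        raise ValueError("empty trajectory")
    counts = np.bincount(states, minlength=n_states).astype(float)
    return 100.0 * counts / counts.sum()


def binned_reward(rewards: np.ndarray, bin_size: int) -> np.ndarray:
    """Sum reward events in contiguous bins of ``bin_size`` steps.

    A trailing partial bin is dropped so that every bin covers the same
    number of steps.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rewards = np.asarray(rewards, dtype=float)
    n_bins = rewards.size // bin_size
    if n_bins == 0:
        return np.zeros(0)
    return rewards[: n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1)
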
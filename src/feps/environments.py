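"""The two behavioral POMDP environments, plus a random-POMDP fixture generator.

Both built-in environments are deterministic, partially observable and
strongly connected:

* ``timed`` — a timed-response Skinner box.  An animal faces a lever; after
  the light turns on it must wait exactly one step before pressing to obtain
  food.  Four hidden states, three compositional observations (the light/
  hunger combinations), two actions.  The observation (light on, hungry) is
  aliased: it is emitted by two hidden states distinguishable only through
  context.
* ``grid3`` — a 3x3 smell-gradient grid.  Food sits in the top-right corner
  and every cell emits an integer smell intensity 0..3 decreasing with
  Manhattan distance to the food, so most intensities are aliased across
  several cells.  Four directional actions; walls clamp.

An environment never exposes its hidden state to the agent, only the
observation it emits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Environment",
    "TimedResponseEnv",
    "GridEnv",
    "make_env",
    "random_pomdp",
    "timed_response_step",
    "grid_obs",
    "grid_step",
    "ENV_REGISTRY",
]


@dataclass
class Environment:
    """A deterministic POMDP: tabular transitions, emissions and initial rule.

    ``transitions[e, a]`` is the successor hidden state, ``obs_map[e]`` the
    emitted observation.  ``initial`` is either a fixed state index or
    ``"uniform"`` for a uniformly random initial state.
    """

    name: str
    transitions: np.ndarray  # (n_states, n_actions) int
    obs_map: np.ndarray  # (n_states,) int
    initial: int | str = "uniform"
    action_names: tuple[str, ...] = ()
    obs_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.int64)
        self.obs_map = np.asarray(self.obs_map, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transitions.shape[1]

    @property
    def n_obs(self) -> int:
        return int(self.obs_map.max()) + 1

    def step(self, e: int, a: int) -> int:
        if not 0 <= a < self.n_actions:
            raise ValueError(f"invalid action index {a}")
        return int(self.transitions[e, a])

    def obs(self, e: int) -> int:
        return int(self.obs_map[e])

    def initial_state(self, rng: np.random.Generator) -> int:
        if self.initial == "uniform":
            return int(rng.integers(self.n_states))
        return int(self.initial)

    def is_strongly_connected(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_states))
        for e in range(self.n_states):
            for a in range(self.n_actions):
                g.add_edge(e, int(self.transitions[e, a]))
        return nx.is_strongly_connected(g)

    # -- JSON environment-description format ------------------------------

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "obs": self.obs_map.tolist(),
            "transitions": self.transitions.tolist(),
            "initial": self.initial,
        }

    @classmethod
    def from_json(cls, doc: dict | str) -> "Environment":
        if isinstance(doc, str):
            doc = json.loads(doc)
        return cls(
            name=doc.get("name", "custom"),
            transitions=np.asarray(doc["transitions"], dtype=np.int64),
            obs_map=np.asarray(doc["obs"], dtype=np.int64),
            initial=doc.get("initial", "uniform"),
        )


# ---------------------------------------------------------------------------
# Timed-response Skinner box
# ---------------------------------------------------------------------------

# Hidden states: E0 (light off, hungry), E1 (light just on), E2 (light on,
# one step waited), E0' (light off, satiated).  Observations: 0 = (off,
# hungry), 1 = (off, satiated), 2 = (on, hungry) — the labels are metadata
# only, the compositionality is not exploited.  Actions: 0 = wait, 1 = press.
E0, E1, E2, E0P = 0, 1, 2, 3
WAIT, PRESS = 0, 1

_TIMED_OBS = np.array([0, 2, 2, 1], dtype=np.int64)
_TIMED_OBS_NAMES = ("light off, hungry", "light off, satiated", "light on, hungry")
_TIMED_ACTION_NAMES = ("wait", "press")


def timed_response_step(e: int, a: int) -> int:
    """Hidden-state transition of the timed-response task.

    From E0 the light turns on regardless of the action.  From E1 (light just
    on) pressing is too early and resets to E0; waiting advances to E2.  From
    E2 pressing on time reaches satiation E0'.  The two remaining arrows are
    not pinned down by the task description and are chosen here: waiting in
    E2 misses the window and resets to E0, and satiation lasts a single step
    (E0' returns to E0 regardless of the action) so that long episodes keep
    cycling.
    """
    if a not in (WAIT, PRESS):
        raise ValueError(f"invalid action index {a}")
    if e == E0:
        return E1
    if e == E1:
        return E2 if a == WAIT else E0
    if e == E2:
        return E0P if a == PRESS else E0
    if e == E0P:
        return E0
    raise ValueError(f"invalid state index {e}")


def TimedResponseEnv() -> Environment:
    """The four-state timed-response environment, initialized in E0."""
    transitions = np.array(
        [[timed_response_step(e, a) for a in (WAIT, PRESS)] for e in range(4)], dtype=np.int64
    )
    return Environment(
        name="timed",
        transitions=transitions,
        obs_map=_TIMED_OBS.copy(),
        initial=E0,
        action_names=_TIMED_ACTION_NAMES,
        obs_names=_TIMED_OBS_NAMES,
    )


# ---------------------------------------------------------------------------
# 3x3 smell-gradient grid
# ---------------------------------------------------------------------------

# Coordinates are (column, row) with origin (0, 0) at the lower-left corner;
# the food (target placement is configurable) defaults to the top-right cell
# (2, 2).  State index = col + side * row.
RIGHT, LEFT, UP, DOWN = 0, 1, 2, 3
_GRID_ACTION_NAMES = ("right", "left", "up", "down")
_GRID_MOVES = {RIGHT: (1, 0), LEFT: (-1, 0), UP: (0, 1), DOWN: (0, -1)}


def grid_obs(cell: tuple[int, int], food: tuple[int, int] = (2, 2), side: int = 3) -> int:
    """Smell intensity of a cell: max(0, 3 - Manhattan distance to the food)."""
    x, y = cell
    if not (0 <= x < side and 0 <= y < side):
        raise ValueError(f"cell {cell} outside the {side}x{side} grid")
    return max(0, 3 - (abs(x - food[0]) + abs(y - food[1])))


def grid_step(cell: tuple[int, int], a: int, side: int = 3) -> tuple[int, int]:
    """Move one cell in the action's direction, clamping at the walls."""
    if a not in _GRID_MOVES:
        raise ValueError(f"invalid action index {a}")
    x, y = cell
    if not (0 <= x < side and 0 <= y < side):
        raise ValueError(f"cell {cell} outside the {side}x{side} grid")
    dx, dy = _GRID_MOVES[a]
    return (min(side - 1, max(0, x + dx)), min(side - 1, max(0, y + dy)))


def GridEnv(food: tuple[int, int] = (2, 2), side: int = 3) -> Environment:
    """The smell-gradient grid with uniformly random initial cell."""
    n = side * side
    transitions = np.empty((n, 4), dtype=np.int64)
    obs_map = np.empty(n, dtype=np.int64)
    for y in range(side):
        for x in range(side):
            e = x + side * y
            obs_map[e] = grid_obs((x, y), food=food, side=side)
            for a in range(4):
                nx_, ny_ = grid_step((x, y), a, side=side)
                transitions[e, a] = nx_ + side * ny_
    return Environment(
        name="grid3" if side == 3 else f"grid{side}",
        transitions=transitions,
        obs_map=obs_map,
        initial="uniform",
        action_names=_GRID_ACTION_NAMES,
        obs_names=tuple(f"smell {i}" for i in range(int(obs_map.max()) + 1)),
    )


# ---------------------------------------------------------------------------
# Random deterministic POMDP fixtures
# ---------------------------------------------------------------------------


def random_pomdp(n_states: int, n_obs: int, n_actions: int, seed: int) -> Environment:
    """A random small deterministic POMDP, reproducible by seed.

    Transitions are sampled uniformly over states; the emission map is
    surjective onto the observations.
    """
    if n_obs > n_states:
        raise ValueError("n_obs may not exceed n_states")
    rng = np.random.Generator(np.random.PCG64(seed))
    transitions = rng.integers(n_states, size=(n_states, n_actions))
    obs_map = np.concatenate(
        [np.arange(n_obs), rng.integers(n_obs, size=n_states - n_obs)]
    ).astype(np.int64)
    rng.shuffle(obs_map)
    return Environment(
        name=f"random_pomdp_{seed}",
        transitions=transitions,
        obs_map=obs_map,
        initial="uniform",
    )


ENV_REGISTRY = {
    "timed": TimedResponseEnv,
    "grid3": GridEnv,
}


def make_env(name: str) -> Environment:
    """Instantiate a registered environment by name (``timed`` or ``grid3``)."""
    try:
        return ENV_REGISTRY[name]()
    except KeyError:
        raise ValueError(f"unknown environment {name!r}; known: {sorted(ENV_REGISTRY)}") from None
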
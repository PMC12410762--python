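"""Shared fixtures: small hand-built world models and session-scoped
trained populations reused by the slower behavioural tests."""

from __future__ import annotations

import numpy as np
import pytest

from feps import (
    CloneMap,
    EdgeBundle,
    RunConfig,
    WorldModel,
    make_env,
    train,
)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def perfect_timed_model() -> WorldModel:
    """Hand-built exact copy of the timed-response task.

    Two clones per observation; clone 0 of the light-on observation plays
    the 'light just turned on' state and clone 1 the 'waited one step'
    state.  Beliefs: 0,1 = clones of (off,hungry); 2,3 = (off,satiated);
    4,5 = (on,hungry).
    """
    wm = WorldModel.fresh(n_obs=3, n_clones=2, n_actions=2, h0=1e-9)
    E0c, E0pc, E1c, E2c = 0, 2, 4, 5
    WAIT, PRESS = 0, 1
    edges = {
        (E0c, WAIT): E1c, (E0c, PRESS): E1c,
        (E1c, WAIT): E2c, (E1c, PRESS): E0c,
        (E2c, PRESS): E0pc, (E2c, WAIT): E0c,
        (E0pc, WAIT): E0c, (E0pc, PRESS): E0c,
    }
    for (b, a), b2 in edges.items():
        wm.prior.h[a, b, :] = 1e-9
        wm.prior.h[a, b, b2] = 1.0
    # unused duplicate clones self-loop harmlessly
    for b in (1, 3):
        for a in (0, 1):
            wm.prior.h[a, b, :] = 1e-9
            wm.prior.h[a, b, edges[(b - 1, a)]] = 1.0
    wm.posterior.h[:] = wm.prior.h
    return wm


def perfect_grid_model() -> WorldModel:
    """Hand-built exact copy of the 3x3 smell grid (3 clones/observation).

    Clone j of observation s is assigned to the j-th cell emitting s (cells
    ordered by state index); surplus clones duplicate the last such cell.
    """
    env = make_env("grid3")
    wm = WorldModel.fresh(n_obs=4, n_clones=3, n_actions=4, h0=1e-9)
    cells_of_obs = {s: [e for e in range(9) if env.obs(e) == s] for s in range(4)}
    cell_of_clone = {}
    clone_of_cell = {}
    for s, cells in cells_of_obs.items():
        for j in range(3):
            b = s * 3 + j
            cell = cells[min(j, len(cells) - 1)]
            cell_of_clone[b] = cell
            if j < len(cells):
                clone_of_cell[cell] = b if cell not in clone_of_cell else clone_of_cell[cell]
    for b, cell in cell_of_clone.items():
        for a in range(4):
            nxt_cell = env.step(cell, a)
            nxt_clone = clone_of_cell[nxt_cell]
            wm.prior.h[a, b, :] = 1e-9
            wm.prior.h[a, b, nxt_clone] = 1.0
    wm.posterior.h[:] = wm.prior.h
    return wm


@pytest.fixture(scope="session")
def perfect_timed():
    return perfect_timed_model()


@pytest.fixture(scope="session")
def perfect_grid():
    return perfect_grid_model()


@pytest.fixture(scope="session")
def timed_trained():
    """Populations of 20 timed-task agents, explore and task modes."""
    return {
        "explore": train(RunConfig.defaults("timed", pref_mode="explore", zeta=0.0, seed=1)),
        "task": train(RunConfig.defaults("timed", pref_mode="task", zeta=-1.0, seed=1)),
    }


@pytest.fixture(scope="session")
def grid_settings():
    """Five grid populations (5 agents, 15000 episodes) across the policy
    settings: uniform, task-oriented +/-3, explorative +1/+3."""
    runs = {}
    for key, mode, zeta in [
        ("zeta0", "explore", 0.0),
        ("task-3", "task", -3.0),
        ("task+3", "task", 3.0),
        ("explore+1", "explore", 1.0),
        ("explore+3", "explore", 3.0),
    ]:
        runs[key] = train(RunConfig.defaults("grid3", pref_mode=mode, zeta=zeta, seed=1))
    return runs


@pytest.fixture(scope="session")
def grid_full():
    """Uniform-policy grid population at the full 40000-episode budget."""
    return train(
        RunConfig.defaults("grid3", pref_mode="explore", zeta=0.0, seed=1, n_episodes=40000)
    )
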
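"""Belief-state estimation in superposition.

With aliased observations the agent cannot know which clone clip represents
its true situation.  Instead of committing to a single clip, the filter
keeps every clone compatible with the observation history as a candidate
("excited") clip: actions are chosen by letting the candidates vote through
the policy, each candidate is advanced through the world model, and any
successor whose observation disagrees with the environment is eliminated.
This is a support-only Bayes filter — the deterministic clone emission
zeroes incompatible candidates and the posterior over survivors is kept
uniform.  When every candidate dies (an imperfect model predicted wrong for
all of them) the hypothesis restarts from all clones of the current
observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .policy_efe import PolicyTable
from .world_model import CloneMap, WorldModel, _sample_index, transition_prob

__all__ = ["Hypothesis", "init_hypothesis", "vote_action", "advance"]


@dataclass
class Hypothesis:
    """The nonempty set of candidate belief clips, kept sorted for
    deterministic iteration, plus the successors sampled for each candidate
    in the step being resolved."""

    candidates: list[int]
    pending: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("hypothesis must be nonempty")
        self.candidates = sorted(set(int(c) for c in self.candidates))


def init_hypothesis(clone_map: CloneMap, s0: int) -> Hypothesis:
    """All clones of the observed sensory state are candidates."""
    return Hypothesis(candidates=[int(b) for b in clone_map.clones_of(s0)])


def vote_action(
    h: Hypothesis,
    policy: PolicyTable,
    rng: np.random.Generator,
    exact_mixture: bool = False,
) -> int:
    """Let the candidates vote for the next action.

    Each candidate samples one action from its policy row; the empirical
    vote frequencies are normalized and the action is sampled from them.
    With ``exact_mixture=True`` the intermediate sampling is skipped and the
    action is drawn from the exact uniform mixture of the candidates' policy
    rows instead.
    """
    n_actions = policy.pi.shape[1]
    if exact_mixture:
        mixture = policy.pi[h.candidates].mean(axis=0)
        return _sample_index(mixture, rng.random())
    votes = np.zeros(n_actions)
    for c in h.candidates:
        votes[_sample_index(policy.pi[c], rng.random())] += 1.0
    return _sample_index(votes / votes.sum(), rng.random())


def advance(
    h: Hypothesis,
    wm: WorldModel,
    a: int,
    s_env: int,
    rng: np.random.Generator,
    argmax: bool = False,
) -> tuple[Hypothesis, bool]:
    """Advance every candidate one step and eliminate mismatches.

    For each candidate a successor clip is sampled from the prior transition
    row of (candidate, a) (or taken as the row argmax with ``argmax=True``).
    Successors whose observation equals ``s_env`` survive; duplicates merge
    (excitations are binary, one per clip).  If no successor survives the
    hypothesis restarts from all clones of ``s_env``.

    Returns the new hypothesis and whether the step counted as a correct
    prediction (at least one sampled successor matched ``s_env``).
    """
    obs_of = wm.clone_map.obs_of
    pending: dict[int, int] = {}
    for c in h.candidates:
        row = wm.prior.h[a, c]
        if argmax:
            nxt = int(np.argmax(row))
        else:
            nxt = _sample_index(transition_prob(row), rng.random())
        pending[c] = nxt
    survivors = sorted({nxt for nxt in pending.values() if obs_of[nxt] == s_env})
    matched = bool(survivors)
    if not survivors:
        return init_hypothesis(wm.clone_map, s_env), False
    return Hypothesis(candidates=survivors, pending=pending), matched
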
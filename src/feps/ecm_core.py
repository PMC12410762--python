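"""Graph-memory primitives of the episodic and compositional memory (ECM).

The agent's memory is a directed graph of "clips" whose edges carry a
trainable weight, the *h-value*.  Normalizing a group of h-values row-wise
yields transition probabilities; learning raises the h-values of useful edges
and a forgetting term relaxes every updated edge back toward its initial
value ``h0``.

On top of the plain h-value machinery this module implements the
confidence-weighted internal reward: while the agent's sensory predictions
keep coming true, the edges that produced them accumulate an integer
*confidence* ``f``; when a prediction finally fails (or the episode ends) the
open run of correct predictions — the *trajectory* — is closed and every edge
on it receives a reward proportional to its confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EdgeBundle",
    "TrajectoryRecord",
    "TrajectoryStep",
    "transition_prob",
    "bump_confidence",
    "close_trajectory",
]


def transition_prob(h_row: np.ndarray, sharpen: bool = False) -> np.ndarray:
    """Normalize a row of h-values into a probability vector.

    p(j) = h_j / sum_k h_k.  The row must be non-negative with at least one
    strictly positive entry; an all-zero row signals an uninitialized or
    degenerate edge group and raises ``ValueError``.

    ``sharpen=True`` applies a softmax over the h-values instead of plain
    normalization, enhancing probability differences in large memories; it
    is off everywhere by default.
    """
    h_row = np.asarray(h_row, dtype=float)
    if np.any(h_row < 0):
        raise ValueError("h-values must be non-negative")
    total = h_row.sum()
    if total <= 0.0:
        raise ValueError("degenerate edge group: all h-values are zero")
    if sharpen:
        z = np.exp(h_row - h_row.max())
        return z / z.sum()
    return h_row / total


@dataclass
class TrajectoryStep:
    """One deliberation step: a sampled edge and the outcome of its prediction."""

    belief_from: int
    action: int
    belief_to: int
    predicted_obs: int
    env_obs: int
    matched: bool


@dataclass
class TrajectoryRecord:
    """The open run of consecutive correct predictions.

    All steps except possibly the last are matched; ``length`` counts the
    matched steps.
    """

    steps: list[TrajectoryStep] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(1 for s in self.steps if s.matched)

    def append(self, step: TrajectoryStep) -> None:
        if self.steps and not self.steps[-1].matched:
            raise ValueError("trajectory already interrupted by a mismatch")
        self.steps.append(step)

    def edges(self) -> list[tuple[int, int, int]]:
        """Distinct (action, belief_from, belief_to) edges, in order of first use."""
        seen: dict[tuple[int, int, int], None] = {}
        for s in self.steps:
            seen.setdefault((s.action, s.belief_from, s.belief_to), None)
        return list(seen)


@dataclass
class EdgeBundle:
    """Per-action h-value and confidence tables over directed belief-clip edges.

    ``h`` has shape (n_actions, n_beliefs, n_beliefs); ``f`` is the integer
    confidence table of the same shape, non-zero only on the currently open
    trajectory.  ``h0`` is the shared initial h-value, ``gamma`` the
    forgetting rate in [0, 1] and ``R`` the reward scale.
    """

    h: np.ndarray
    h0: float = 1.0
    gamma: float = 0.01
    R: float = 1.0
    f: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 3 or self.h.shape[1] != self.h.shape[2]:
            raise ValueError("h must have shape (n_actions, n_beliefs, n_beliefs)")
        if np.any(self.h < 0):
            raise ValueError("h-values must be non-negative")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.R <= 0:
            raise ValueError("reward scale R must be positive")
        if self.f is None:
            self.f = np.zeros(self.h.shape, dtype=np.int64)
        else:
            self.f = np.asarray(self.f, dtype=np.int64)

    @classmethod
    def uniform(
        cls, n_actions: int, n_beliefs: int, h0: float = 1.0, gamma: float = 0.01, R: float = 1.0
    ) -> "EdgeBundle":
        return cls(h=np.full((n_actions, n_beliefs, n_beliefs), float(h0)), h0=h0, gamma=gamma, R=R)

    @property
    def n_actions(self) -> int:
        return self.h.shape[0]

    @property
    def n_beliefs(self) -> int:
        return self.h.shape[1]

    def transition_prob(self, a: int, b: int) -> np.ndarray:
        return transition_prob(self.h[a, b])

    def copy(self) -> "EdgeBundle":
        return EdgeBundle(h=self.h.copy(), h0=self.h0, gamma=self.gamma, R=self.R, f=self.f.copy())

    # -- serialization -----------------------------------------------------
    # Confidence is transient (it only lives on the open trajectory) and is
    # not serialized.

    def to_json(self) -> dict:
        return {
            "actions": list(range(self.n_actions)),
            "h": self.h.tolist(),
            "h0": self.h0,
            "gamma": self.gamma,
            "R": self.R,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "EdgeBundle":
        return cls(h=np.asarray(doc["h"], dtype=float), h0=doc["h0"], gamma=doc["gamma"], R=doc["R"])


def bump_confidence(traj: TrajectoryRecord, bundle: EdgeBundle) -> EdgeBundle:
    """Credit a verified prediction to every edge on the open trajectory.

    Called once per verified prediction, after the confirming step has been
    appended: the confidence ``f`` of every *distinct* edge on the trajectory
    increases by one.  An edge used at step n therefore ends the trajectory
    with f = (number of verified steps from its first use to the end).
    An edge that re-occurs within the trajectory is still counted once per
    verified step, not once per occurrence (a per-occurrence variant would
    add the increments of each occurrence separately; the set reading is the
    one used throughout).

    Mutates ``bundle.f`` in place and returns the bundle.
    """
    if traj.steps and not traj.steps[-1].matched:
        raise ValueError("confidence only grows on verified predictions")
    for a, bf, bt in traj.edges():
        bundle.f[a, bf, bt] += 1
    return bundle


def close_trajectory(
    traj: TrajectoryRecord, bundle: EdgeBundle, decay_scope: str = "trajectory"
) -> EdgeBundle:
    """Distribute the confidence-weighted rewards and reset the trajectory.

    Every edge on the trajectory is updated as

        h <- h - gamma * (h - h0) + f * R

    so rewarded edges (f > 0) grow while the final, mismatched edge — whose
    prediction failed and whose confidence is still zero — only decays toward
    ``h0``.  With ``decay_scope="global"`` the forgetting term is applied to
    every edge of the bundle instead of only those on the trajectory.
    Confidences are reset to zero afterwards.
    """
    if decay_scope not in ("trajectory", "global"):
        raise ValueError(f"unknown decay_scope {decay_scope!r}")
    if decay_scope == "global":
        bundle.h -= bundle.gamma * (bundle.h - bundle.h0)
        for a, bf, bt in traj.edges():
            bundle.h[a, bf, bt] += bundle.f[a, bf, bt] * bundle.R
    else:
        for a, bf, bt in traj.edges():
            h = bundle.h[a, bf, bt]
            bundle.h[a, bf, bt] = h - bundle.gamma * (h - bundle.h0) + bundle.f[a, bf, bt] * bundle.R
    bundle.f[:] = 0
    return bundle
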
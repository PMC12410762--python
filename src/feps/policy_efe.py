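"""Expected free energy (EFE) over one-step futures and the softmax policy.

For a candidate action a taken from belief clip b the EFE is

    G_b[a] = -H[B' | b, a] + E_{b',s' ~ p(.|b,a)}[ -log p_ref(s', b' | b) ]

i.e. the negative entropy of the predicted belief plus the expected surprise
of the outcome under the preference distribution.  The policy is the
row-wise softmax pi(a|b) = softmax(zeta * G_b)[a]: negative scaling zeta
favours low-EFE (preference-satisfying, uncertainty-avoiding) actions, zeta
= 0 is the uniform policy and positive zeta favours high-EFE actions.

Two preference modes are supported:

* ``task`` — the preference factorizes into an absolute distribution over
  observations (probability p* on the target observation, the rest uniform)
  times a look-ahead distribution over belief transitions built by the
  planner.
* ``exploration`` — the preference is the action-marginal of the world model
  itself; the EFE then reduces exactly to the information gain
  KL[p(B'|b,a) || p(B'|b)] about the next belief, and running with positive
  zeta drives the agent toward transitions its model has not yet resolved
  (escaping the "Dark Room" of maximally predictable states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .world_model import WorldModel

__all__ = [
    "LOG_FLOOR",
    "PreferenceSpec",
    "PolicyTable",
    "abs_pref_vector",
    "efe",
    "efe_matrix",
    "exploration_pref",
    "efe_exploration",
    "policy_from_efe",
]

#: Floor applied inside logarithms of preference probabilities; keeps the EFE
#: finite when a preference entry is exactly zero (e.g. argmax-collapsed
#: look-ahead rows).
LOG_FLOOR = 1e-12


def abs_pref_vector(n_obs: int, target_obs: int, pstar: float = 0.95) -> np.ndarray:
    """Absolute preference over observations: p* on the target, rest uniform."""
    if not 0.0 < pstar < 1.0:
        raise ValueError("pstar must lie in (0, 1)")
    if not 0 <= target_obs < n_obs:
        raise ValueError(f"invalid target observation {target_obs}")
    pref = np.full(n_obs, (1.0 - pstar) / (n_obs - 1))
    pref[target_obs] = pstar
    return pref


@dataclass
class PreferenceSpec:
    """Preference distribution entering the EFE.

    In ``task`` mode the joint preference over (s', b') conditioned on b is
    ``abs_pref[s'] * lookahead[b, b']``; in ``exploration`` mode it is the
    action-marginal of the world model under the policy the preference was
    built from, stored directly as ``lookahead`` with a flat absolute part (the
    clone structure collapses the observation dependence).
    """

    mode: str  # "task" | "exploration"
    abs_pref: np.ndarray | None = None  # (n_obs,)
    lookahead: np.ndarray | None = None  # (n_beliefs, n_beliefs), rows sum to 1
    #: Floor for zero look-ahead entries inside the EFE log.  ``None`` means
    #: the uniform value 1/N_B — the training-time choice, which keeps the
    #: utility term on the same scale as the entropy term so the softmax
    #: policy stays soft.  Argmax-collapsed (evaluation) preferences set it
    #: to the absolute floor instead: off-preference transitions are then
    #: effectively forbidden and the policy is near-greedy at any zeta <= -1.
    look_floor: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("task", "exploration"):
            raise ValueError(f"unknown preference mode {self.mode!r}")
        if self.abs_pref is not None:
            self.abs_pref = np.asarray(self.abs_pref, dtype=float)
        if self.lookahead is not None:
            self.lookahead = np.asarray(self.lookahead, dtype=float)

    def joint(self, wm: WorldModel, b: int) -> np.ndarray:
        """Joint preference p_ref(b', s' | b) as an (n_beliefs, n_obs) table."""
        nb, ns = wm.n_beliefs, wm.n_obs
        obs_of = wm.clone_map.obs_of
        out = np.zeros((nb, ns))
        if self.mode == "exploration":
            # the marginal already carries the emission: mass only on each
            # clip's own observation
            out[np.arange(nb), obs_of] = self.lookahead[b]
        else:
            out = self.abs_pref[None, :] * self.lookahead[b][:, None]
        return out


@dataclass
class PolicyTable:
    """EFE values per (belief, action) and the induced softmax policy."""

    G: np.ndarray  # (n_beliefs, n_actions)
    zeta: float
    pi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if not np.all(np.isfinite(self.G)):
            raise ValueError("EFE matrix contains non-finite entries")
        z = self.zeta * self.G
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        self.pi = e / e.sum(axis=1, keepdims=True)

    @classmethod
    def uniform(cls, n_beliefs: int, n_actions: int) -> "PolicyTable":
        return cls(G=np.zeros((n_beliefs, n_actions)), zeta=0.0)

    def to_json(self) -> dict:
        return {"G": self.G.tolist(), "zeta": self.zeta, "pi": self.pi.tolist()}

    @classmethod
    def from_json(cls, doc: dict) -> "PolicyTable":
        table = cls(G=np.asarray(doc["G"], dtype=float), zeta=doc["zeta"])
        return table


def policy_from_efe(G: np.ndarray, zeta: float) -> PolicyTable:
    """Row-wise softmax policy pi(a|b) = softmax(zeta * G[b])[a]."""
    return PolicyTable(G=G, zeta=zeta)


# ---------------------------------------------------------------------------
# Generic EFE evaluator
# ---------------------------------------------------------------------------


def efe(wm: WorldModel, pref: PreferenceSpec, b: int, a: int) -> float:
    """EFE of taking action a from belief b under the given preference.

    Evaluates -H[B'|b,a] + sum_{b'} p(b'|b,a) * (-log p_ref(obs(b'), b'|b)):
    the deterministic emission collapses the sum over observations onto each
    clip's own observation.  Zero preference entries are floored inside the
    log.
    """
    p = wm.transition_matrix(a)[b]
    nz = p > 0
    neg_entropy = float(np.sum(p[nz] * np.log(p[nz])))
    obs_of = wm.clone_map.obs_of
    if pref.mode == "task":
        # Factorized preference; each factor's log is guarded separately.
        look_floor = 1.0 / wm.n_beliefs if pref.look_floor is None else pref.look_floor
        log_pref = np.log(np.maximum(pref.abs_pref[obs_of], LOG_FLOOR)) + np.log(
            np.maximum(pref.lookahead[b], look_floor)
        )
    else:
        joint = pref.joint(wm, b)
        pref_own = joint[np.arange(wm.n_beliefs), obs_of]
        log_pref = np.log(np.maximum(pref_own, LOG_FLOOR))
    surprise = float(-np.sum(p[nz] * log_pref[nz]))
    return neg_entropy + surprise


def efe_matrix(wm: WorldModel, pref: PreferenceSpec) -> np.ndarray:
    """EFE of every (belief, action) pair as an (n_beliefs, n_actions) matrix."""
    nb, na = wm.n_beliefs, wm.n_actions
    G = np.empty((nb, na))
    for b in range(nb):
        for a in range(na):
            G[b, a] = efe(wm, pref, b, a)
    return G


# ---------------------------------------------------------------------------
# Exploration preference = action-marginal of the world model
# ---------------------------------------------------------------------------


def exploration_pref(wm: WorldModel, policy: PolicyTable) -> PreferenceSpec:
    """Preference for transitions the model itself predicts, marginalized
    over actions of the supplied policy:

        p_ref(b' | b) = sum_a pi(a|b) * p(b'|b, a)

    (the joint over (b', s') follows by attaching the deterministic
    emission).  Plugged into the generic EFE this makes the EFE equal to the
    information gain about the next belief state.
    """
    na = wm.n_actions
    trans = np.stack([wm.transition_matrix(a) for a in range(na)])  # (na, nb, nb)
    marginal = np.einsum("ba,abj->bj", policy.pi, trans)
    return PreferenceSpec(mode="exploration", lookahead=marginal)


def efe_exploration(wm: WorldModel, policy: PolicyTable, b: int, a: int) -> float:
    """Closed-form exploration EFE: the information gain

        KL[ p(B'|b,a) || sum_a' pi(a'|b) p(B'|b,a') ]  >=  0.

    Identical (within numerical error) to evaluating the generic EFE with
    ``exploration_pref``.
    """
    p = wm.transition_matrix(a)[b]
    trans = np.stack([wm.transition_matrix(ap)[b] for ap in range(wm.n_actions)])
    marginal = policy.pi[b] @ trans
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / np.maximum(marginal[nz], LOG_FLOOR))))


def efe_exploration_matrix(wm: WorldModel, policy: PolicyTable) -> np.ndarray:
    """Exploration EFE for every (belief, action) pair."""
    nb, na = wm.n_beliefs, wm.n_actions
    G = np.empty((nb, na))
    for b in range(nb):
        for a in range(na):
            G[b, a] = efe_exploration(wm, policy, b, a)
    return G
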
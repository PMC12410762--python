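"""One-shot inference of a goal-directed policy from a trained world model.

Planning never touches the environment.  Given a target observation, the
planner iterates (``k_pref`` times, starting from a uniform policy):

1. *reachability* — marginalize the transition tables over the current
   policy: r(b'|b) = sum_a p(b'|b,a) pi(a|b);
2. *value propagation* — seed each clip with the absolute preference of its
   observation and let values flow backwards for ``horizon`` steps, each
   clip taking the best discounted reachable value:
   v_n(b) = max{ v_{n-1}(b), max_{b+} beta^{n-1} r(b+|b) v_{n-1}(b+) };
3. *look-ahead preference* — restrict each row to the "children" of b (the
   successors whose reachability exceeds the row mean) and renormalize the
   propagated values over them;
4. a new policy via the EFE and the softmax with the configured zeta.

Values can only increase during propagation, so the preference for the
target observation spreads to the intermediate belief states that lead to
it, and a single EFE evaluation then yields a policy that is optimal
whenever the model is an accurate copy of the environment and the horizon
covers its diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .policy_efe import (
    LOG_FLOOR,
    PolicyTable,
    PreferenceSpec,
    abs_pref_vector,
    efe_matrix,
    policy_from_efe,
)
from .world_model import WorldModel

__all__ = [
    "PlannerConfig",
    "ValueTable",
    "reachability",
    "initial_value",
    "propagate_values",
    "lookahead_pref",
    "infer_policy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlannerConfig:
    """Planner hyperparameters.

    ``horizon`` is the number of value-propagation steps (>= 1, at least the
    graph diameter for optimal plans), ``beta`` the per-step discount in
    [0, 1], ``k_pref`` the number of policy-refinement iterations and
    ``zeta`` the softmax scaling of the resulting policy.  ``pref_argmax``
    collapses each look-ahead preference row to a point mass on its best
    transition (the evaluation-time default).
    """

    horizon: int = 2
    beta: float = 0.5
    k_pref: int = 1
    zeta: float = -1.0
    pstar: float = 0.95
    pref_argmax: bool = True

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.k_pref < 1:
            raise ValueError("k_pref must be >= 1")


@dataclass
class ValueTable:
    """Belief-state values after n propagation steps (monotone in n)."""

    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)


def reachability(wm: WorldModel, policy: PolicyTable) -> np.ndarray:
    """Policy-marginalized transition probabilities r(b'|b); rows sum to 1."""
    trans = np.stack([wm.transition_matrix(a) for a in range(wm.n_actions)])
    return np.einsum("ba,abj->bj", policy.pi, trans)


def initial_value(wm: WorldModel, abs_pref: np.ndarray) -> ValueTable:
    """Seed values: each clip inherits the absolute preference of its
    observation (a single term, by the deterministic clone emission)."""
    return ValueTable(v=np.asarray(abs_pref, dtype=float)[wm.clone_map.obs_of])


def propagate_values(
    v0: ValueTable, r: np.ndarray, beta: float, horizon: int
) -> ValueTable:
    """Backward value propagation over the reachability graph.

    For n = 1..horizon each clip either keeps its value or takes the best
    discounted value beta^(n-1) * r(b+|b) * v_{n-1}(b+) among its
    successors; values are therefore non-decreasing elementwise.  Ties in
    the max resolve to the lowest clip index (plain max over values).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    v = v0.v.copy()
    for n in range(1, horizon + 1):
        candidate = (beta ** (n - 1)) * (r * v[None, :]).max(axis=1)
        v = np.maximum(v, candidate)
    return ValueTable(v=v)


def lookahead_pref(v: ValueTable, r: np.ndarray) -> np.ndarray:
    """Look-ahead preference rows over the children of each belief.

    ch(b) = {b+ : r(b+|b) strictly above the row mean}; the preference is
    the propagated value renormalized over ch(b) and zero outside.  A
    uniform reachability row has no children (strict inequality) and an
    all-zero child value row cannot be normalized; both fall back to a
    uniform row (over the children if any, else over all beliefs) and are
    logged.
    """
    nb = r.shape[0]
    pref = np.zeros((nb, nb))
    row_mean = r.mean(axis=1)
    for b in range(nb):
        children = r[b] > row_mean[b]
        if not children.any():
            logger.debug("lookahead_pref: belief %d has no children, uniform fallback", b)
            pref[b] = 1.0 / nb
            continue
        weights = np.where(children, v.v, 0.0)
        total = weights.sum()
        if total <= 0.0:
            logger.debug("lookahead_pref: belief %d children all zero-valued, uniform fallback", b)
            pref[b, children] = 1.0 / children.sum()
        else:
            pref[b] = weights / total
    return pref


def _argmax_collapse(pref: np.ndarray) -> np.ndarray:
    """Keep only the maximal-preference transition of each row (point mass)."""
    out = np.zeros_like(pref)
    out[np.arange(pref.shape[0]), pref.argmax(axis=1)] = 1.0
    return out


def infer_policy(
    wm: WorldModel,
    target_obs: int,
    cfg: PlannerConfig,
    init_policy: PolicyTable | None = None,
) -> PolicyTable:
    """Goal-directed policy for ``target_obs``, inferred in one shot.

    Runs ``cfg.k_pref`` refinement iterations starting from a uniform policy
    (or ``init_policy``); each iteration rebuilds the reachability, the
    propagated values and the look-ahead preference, evaluates the EFE under
    the factorized task preference and applies the softmax with
    ``cfg.zeta``.  The world model is read-only throughout — no environment
    handle exists and a target change costs nothing but this call.
    """
    abs_pref = abs_pref_vector(wm.n_obs, target_obs, pstar=cfg.pstar)
    policy = init_policy or PolicyTable.uniform(wm.n_beliefs, wm.n_actions)
    for _ in range(cfg.k_pref):
        r = reachability(wm, policy)
        v = propagate_values(initial_value(wm, abs_pref), r, cfg.beta, cfg.horizon)
        pref_rows = lookahead_pref(v, r)
        if cfg.pref_argmax:
            # a point-mass preference row forbids the other transitions, so
            # their log is floored absolutely and the policy is near-greedy
            pref_rows = _argmax_collapse(pref_rows)
            pref = PreferenceSpec(
                mode="task", abs_pref=abs_pref, lookahead=pref_rows, look_floor=LOG_FLOOR
            )
        else:
            pref = PreferenceSpec(mode="task", abs_pref=abs_pref, lookahead=pref_rows)
        policy = policy_from_efe(efe_matrix(wm, pref), cfg.zeta)
    return policy
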
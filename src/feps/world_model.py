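"""Clone-structured generative world model.

The agent's latent space is a fixed set of *clone clips*: each observation s
owns ``n_clones`` belief clips, so the emission likelihood p(s|b) is the
deterministic indicator of b's parent observation and only the
action-conditioned transition tables between clips are learned.  Two copies
of the transition table coexist: behaviour samples from the *prior* while
the confidence-weighted rewards land in the *posterior*; the prior is
replaced by the posterior once per episode (``sync_prior``).

The per-step variational free energy (VFE) reported during training is

    KL[q(B | b, a) || p(B | b, a)]  +  E_{b' ~ q}[ -log p~(s_env | b') ]

where q and p are the posterior and prior transition rows actually used and
p~ is an epsilon-smoothed emission (the literal deterministic emission makes
the surprise infinite whenever posterior mass sits on clones of another
observation; the smoothing keeps the learning curves finite).  The smoothed
emission is used for this metric only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .ecm_core import (
    EdgeBundle,
    TrajectoryRecord,
    TrajectoryStep,
    bump_confidence,
    close_trajectory,
    transition_prob,
)

__all__ = [
    "CloneMap",
    "WorldModel",
    "AgentState",
    "VFE_EPS",
    "sample_next_belief",
    "predict_observation",
    "training_step",
    "sync_prior",
    "step_vfe",
]

#: Emission smoothing used by the VFE metric only: p~(s|b) = 1 - eps when s
#: is b's observation, eps / (N_S - 1) otherwise.
VFE_EPS = 1e-3


@dataclass(frozen=True)
class CloneMap:
    """Fixed assignment of belief clips to observations.

    Clip ``s * n_clones + j`` is clone j of observation s, so there are
    ``n_beliefs = n_obs * n_clones`` clips and the emission function is the
    deterministic map ``obs_of``.
    """

    n_obs: int
    n_clones: int

    @property
    def n_beliefs(self) -> int:
        return self.n_obs * self.n_clones

    @property
    def obs_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_obs), self.n_clones)

    def obs(self, b: int) -> int:
        if not 0 <= b < self.n_beliefs:
            raise ValueError(f"invalid belief index {b}")
        return b // self.n_clones

    def clones_of(self, s: int) -> np.ndarray:
        if not 0 <= s < self.n_obs:
            raise ValueError(f"invalid observation index {s}")
        return np.arange(s * self.n_clones, (s + 1) * self.n_clones)

    def to_json(self) -> dict:
        return {"n_obs": self.n_obs, "n_clones": self.n_clones}

    @classmethod
    def from_json(cls, doc: dict) -> "CloneMap":
        return cls(n_obs=doc["n_obs"], n_clones=doc["n_clones"])


@dataclass
class WorldModel:
    """Clone map plus prior/posterior transition bundles."""

    clone_map: CloneMap
    prior: EdgeBundle
    posterior: EdgeBundle
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nb = self.clone_map.n_beliefs
        if self.prior.h.shape != self.posterior.h.shape:
            raise ValueError("prior and posterior must have identical shape")
        if self.prior.n_beliefs != nb:
            raise ValueError("transition tables do not match the clone map")

    @classmethod
    def fresh(
        cls,
        n_obs: int,
        n_clones: int,
        n_actions: int,
        h0: float = 1.0,
        gamma: float = 0.01,
        R: float = 1.0,
    ) -> "WorldModel":
        cm = CloneMap(n_obs=n_obs, n_clones=n_clones)
        prior = EdgeBundle.uniform(n_actions, cm.n_beliefs, h0=h0, gamma=gamma, R=R)
        posterior = EdgeBundle.uniform(n_actions, cm.n_beliefs, h0=h0, gamma=gamma, R=R)
        return cls(clone_map=cm, prior=prior, posterior=posterior)

    @property
    def n_actions(self) -> int:
        return self.prior.n_actions

    @property
    def n_beliefs(self) -> int:
        return self.clone_map.n_beliefs

    @property
    def n_obs(self) -> int:
        return self.clone_map.n_obs

    def transition_matrix(self, a: int, table: str = "prior") -> np.ndarray:
        """Row-normalized transition probabilities p(b'|b, a)."""
        bundle = self.prior if table == "prior" else self.posterior
        h = bundle.h[a]
        return h / h.sum(axis=1, keepdims=True)

    def copy(self) -> "WorldModel":
        return WorldModel(
            clone_map=self.clone_map,
            prior=self.prior.copy(),
            posterior=self.posterior.copy(),
            meta=dict(self.meta),
        )

    # -- serialization -----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "clone_map": self.clone_map.to_json(),
            "prior": self.prior.to_json(),
            "n_actions": self.n_actions,
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, doc: dict) -> "WorldModel":
        prior = EdgeBundle.from_json(doc["prior"])
        return cls(
            clone_map=CloneMap.from_json(doc["clone_map"]),
            prior=prior,
            posterior=prior.copy(),
            meta=doc.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "WorldModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def to_dot(self, prob_floor: float = 0.0) -> str:
        """Graphviz dot text of the argmax transition graph, for inspection."""
        obs_of = self.clone_map.obs_of
        lines = ["digraph world_model {"]
        for b in range(self.n_beliefs):
            lines.append(
                f'  b{b} [label="c{b % self.clone_map.n_clones + 1}(obs {obs_of[b]})"];'
            )
        for a in range(self.n_actions):
            p = self.transition_matrix(a)
            for b in range(self.n_beliefs):
                j = int(np.argmax(p[b]))
                if p[b, j] >= prob_floor:
                    lines.append(f'  b{b} -> b{j} [label="a{a} {p[b, j]:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class AgentState:
    """Current belief clip plus the open prediction trajectory."""

    belief: int
    trajectory: TrajectoryRecord = field(default_factory=TrajectoryRecord)


def argmax_graph_matches(wm: WorldModel, env) -> bool:
    """Whether the model's argmax transition graph is a faithful copy of the
    environment dynamics.

    Explores the product of the argmax graph and the environment from every
    clone of the initial observation paired with every compatible hidden
    state: each visited pair must agree on the emitted observation after
    every action, and at least one start clone must reach a contradiction-
    free cover of all hidden states.  Duplicate clones (several clips
    playing the same hidden state) are handled naturally by the product
    construction; unreachable clips are ignored.
    """
    succ = np.stack(
        [wm.transition_matrix(a).argmax(axis=1) for a in range(wm.n_actions)]
    )  # (n_actions, n_beliefs)
    init_states = (
        range(env.n_states) if env.initial == "uniform" else [int(env.initial)]
    )
    for e0 in init_states:
        s0 = env.obs(e0)
        for c0 in wm.clone_map.clones_of(s0):
            seen = {(int(c0), e0)}
            frontier = [(int(c0), e0)]
            states_covered = {e0}
            ok = True
            while frontier and ok:
                b, e = frontier.pop()
                for a in range(env.n_actions):
                    b2 = int(succ[a, b])
                    e2 = env.step(e, a)
                    if wm.clone_map.obs(b2) != env.obs(e2):
                        ok = False
                        break
                    if (b2, e2) not in seen:
                        seen.add((b2, e2))
                        states_covered.add(e2)
                        frontier.append((b2, e2))
            if ok and len(states_covered) == env.n_states:
                return True
    return False


def config_hash(doc: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _sample_index(prob: np.ndarray, u: float) -> int:
    """Inverse-CDF sample from a probability vector given a uniform draw."""
    return int(np.searchsorted(np.cumsum(prob), u, side="right").clip(0, len(prob) - 1))


def sample_next_belief(wm: WorldModel, b: int, a: int, rng: np.random.Generator) -> int:
    """Sample the successor clip from the prior transition row of (b, a)."""
    return _sample_index(transition_prob(wm.prior.h[a, b]), rng.random())


def predict_observation(wm: WorldModel, b_next: int) -> int:
    """The observation a clip would emit — the deterministic emission map."""
    return wm.clone_map.obs(b_next)


def reset_belief(wm: WorldModel, s_env: int, rng: np.random.Generator) -> int:
    """A uniformly random clone of the observed sensory state.

    Used both at episode start and after a mismatched prediction: the reset
    belief is unspecified by the trajectory mechanism, and the uniform clone
    choice is the maximum-entropy option that lets all clones compete.
    """
    clones = wm.clone_map.clones_of(s_env)
    return int(clones[_sample_index(np.full(len(clones), 1.0 / len(clones)), rng.random())])


def training_step(
    wm: WorldModel,
    state: AgentState,
    a: int,
    s_env: int,
    rng: np.random.Generator,
    decay_scope: str = "trajectory",
) -> tuple[bool, AgentState]:
    """One interaction step of the world-model training loop.

    The agent samples its predicted successor clip from the prior, predicts
    the corresponding observation and compares it with the observation
    ``s_env`` freshly received from the environment.  A verified prediction
    extends the trajectory and bumps every trajectory edge's confidence; a
    mismatch closes the trajectory (rewarding the posterior), resets the
    belief to a random clone of ``s_env`` and starts a new empty trajectory.

    Always consumes exactly two uniform draws from ``rng`` (successor sample
    and reset draw; the latter is discarded on a match) so that fixed-seed
    runs are reproducible independently of the match outcome.
    """
    b_next = sample_next_belief(wm, state.belief, a, rng)
    u_reset = rng.random()
    s_hat = predict_observation(wm, b_next)
    matched = s_hat == s_env
    state.trajectory.append(
        TrajectoryStep(
            belief_from=state.belief,
            action=a,
            belief_to=b_next,
            predicted_obs=s_hat,
            env_obs=s_env,
            matched=matched,
        )
    )
    if matched:
        bump_confidence(state.trajectory, wm.posterior)
        return True, AgentState(belief=b_next, trajectory=state.trajectory)
    close_trajectory(state.trajectory, wm.posterior, decay_scope=decay_scope)
    clones = wm.clone_map.clones_of(s_env)
    new_belief = int(clones[_sample_index(np.full(len(clones), 1.0 / len(clones)), u_reset)])
    return False, AgentState(belief=new_belief, trajectory=TrajectoryRecord())


def sync_prior(wm: WorldModel) -> WorldModel:
    """Replace the prior transition table by the posterior (in place)."""
    wm.prior.h[:] = wm.posterior.h
    return wm


def step_vfe(
    wm: WorldModel, b_prev: int, a_prev: int, s_env: int, eps: float = VFE_EPS
) -> float:
    """Per-step variational free energy of the transition just taken.

    KL between the posterior and prior rows of (b_prev, a_prev) plus the
    posterior-expected surprise of ``s_env`` under the eps-smoothed emission.
    Always finite and >= -log(1 - eps).
    """
    q = transition_prob(wm.posterior.h[a_prev, b_prev])
    p = transition_prob(wm.prior.h[a_prev, b_prev])
    nz = q > 0
    kl = float(np.sum(q[nz] * np.log(q[nz] / p[nz])))
    match_mass = float(q[wm.clone_map.obs_of == s_env].sum())
    n_s = wm.clone_map.n_obs
    surprise = -(
        match_mass * np.log1p(-eps) + (1.0 - match_mass) * np.log(eps / (n_s - 1))
    )
    return kl + surprise
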
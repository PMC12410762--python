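"""Training loops, evaluation protocols, metrics and run configuration.

``train`` runs a population of independent agents on one of the built-in
environments.  Each agent interacts in episodes of fixed length: every step
it samples an action from its current policy, advances the environment,
runs the prediction/confidence update of the world model, and logs the
per-step variational and expected free energies.  At every episode end the
open trajectory is closed (rewards land in the posterior), the prior is
replaced by the posterior, and the policy is refreshed from the new model —
via the exploration (information-gain) preference or via one planner
iteration toward the configured target observation.

Two evaluation protocols mirror the training-free uses of a converged
model: ``eval_predict`` measures how many consecutive observations the
model predicts correctly under a uniform policy (single-clip tracking vs.
superposition filtering), and ``eval_goal`` measures steps-to-target under
a planner-derived policy with superposition belief estimation, against a
uniform-policy baseline.

All randomness derives from a single master seed through per-agent
``SeedSequence`` spawns; a fixed (config, seed) pair reproduces logs,
models and evaluations bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .belief_filter import advance, init_hypothesis, vote_action
from .ecm_core import close_trajectory
from .environments import Environment, make_env
from .planner import PlannerConfig, infer_policy, lookahead_pref, propagate_values, reachability, initial_value
from .policy_efe import (
    PolicyTable,
    PreferenceSpec,
    abs_pref_vector,
    efe_matrix,
    efe_exploration_matrix,
    policy_from_efe,
)
from .world_model import (
    VFE_EPS,
    AgentState,
    WorldModel,
    _sample_index,
    config_hash,
    step_vfe,
    training_step,
    transition_prob,
)

__all__ = [
    "RunConfig",
    "TrainResult",
    "train",
    "eval_predict",
    "eval_goal",
    "default_planner",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Per-environment study conditions: clone counts and episode budgets follow
#: the behavioural protocols (timed task: 2 clones, 4000 episodes of 80
#: steps, 100 agents at full scale; grid: 3 clones, 40000 episodes of 80
#: steps, 30 agents at full scale).  Desk scale reduces the agent counts.
_ENV_DEFAULTS = {
    "timed": dict(
        n_clones=2, n_episodes=4000, n_agents=20, full_agents=100,
        full_episodes=4000, log_window=100, horizon=2, beta=0.5, target_obs=1,
    ),
    "grid3": dict(
        n_clones=3, n_episodes=15000, n_agents=5, full_agents=30,
        full_episodes=40000, log_window=1500, horizon=4, beta=0.9, target_obs=3,
    ),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a training run depends on; hashable into a manifest."""

    env: str
    n_agents: int
    n_episodes: int
    steps_per_episode: int = 80
    n_clones: int = 2
    zeta: float = 0.0
    pref_mode: str = "explore"  # "explore" | "task"
    target_obs: int = 0
    pstar: float = 0.95
    horizon: int = 2
    beta: float = 0.5
    h0: float = 0.1
    gamma: float = 0.01
    R: float = 1.0
    decay_scope: str = "global"
    seed: int = 0
    log_window: int = 100

    def __post_init__(self) -> None:
        if self.pref_mode not in ("explore", "task"):
            raise ValueError(f"unknown pref_mode {self.pref_mode!r}")
        if self.decay_scope not in ("trajectory", "global"):
            raise ValueError(f"unknown decay_scope {self.decay_scope!r}")
        for name in ("n_agents", "n_episodes", "steps_per_episode", "n_clones", "log_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def defaults(
        cls,
        env: str,
        pref_mode: str = "explore",
        zeta: float = 0.0,
        seed: int = 0,
        full_scale: bool = False,
        **overrides,
    ) -> "RunConfig":
        base = dict(_ENV_DEFAULTS[env])
        if full_scale:
            base["n_agents"] = base["full_agents"]
            base["n_episodes"] = base["full_episodes"]
        base.pop("full_agents")
        base.pop("full_episodes")
        base.update(overrides)
        return cls(env=env, pref_mode=pref_mode, zeta=zeta, seed=seed, **base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_json(self) -> dict:
        return asdict(self)

    def manifest(self) -> dict:
        from . import __version__

        return {
            "config": self.to_json(),
            "config_hash": config_hash(self.to_json()),
            "seed": self.seed,
            "package_version": __version__,
        }


def default_planner(env: str, zeta: float = -1.0) -> PlannerConfig:
    """Evaluation-time planner defaults: horizon at least the environment
    diameter (2 for the timed cycle, 4 for the 3x3 grid), a single
    refinement iteration for the timed task and two for the grid.  The grid
    uses a mild discount (beta = 0.9): with a stronger one, values inherited
    across three or four reachability steps drop below the flat non-target
    preference floor and the gradient toward the goal vanishes in the far
    corner."""
    if env == "timed":
        return PlannerConfig(horizon=2, beta=0.5, k_pref=1, zeta=zeta)
    return PlannerConfig(horizon=4, beta=0.9, k_pref=2, zeta=zeta)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    config: RunConfig
    models: list[WorldModel]
    log: pd.DataFrame

    def final_windowed(self, column: str = "traj_len_w") -> np.ndarray:
        """Final-episode windowed statistic, one value per agent."""
        return (
            self.log.sort_values(["agent", "episode"]).groupby("agent")[column].last().to_numpy()
        )


def _agent_streams(cfg: RunConfig, env: Environment, child: np.random.SeedSequence):
    """Pre-draw every random number a training run consumes, in a fixed
    order shared by the fast and reference paths."""
    rng = np.random.Generator(np.random.PCG64(child))
    E, S = cfg.n_episodes, cfg.steps_per_episode
    if env.initial == "uniform":
        starts = rng.integers(env.n_states, size=E)
    else:
        starts = np.full(E, int(env.initial), dtype=np.int64)
    u_init = rng.random(E)
    u_steps = rng.random((E, S, 3))
    return starts.astype(np.int64), u_init, u_steps


def train(cfg: RunConfig, fast: bool = True) -> TrainResult:
    """Train ``cfg.n_agents`` independent agents; returns models and logs."""
    env = make_env(cfg.env)
    n_obs = env.n_obs
    abs_pref = (
        abs_pref_vector(n_obs, cfg.target_obs, cfg.pstar)
        if cfg.pref_mode == "task"
        else np.zeros(n_obs)
    )
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_agents)
    frames = []
    models = []
    for agent_id, child in enumerate(children):
        starts, u_init, u_steps = _agent_streams(cfg, env, child)
        wm = WorldModel.fresh(
            n_obs, cfg.n_clones, env.n_actions, h0=cfg.h0, gamma=cfg.gamma, R=cfg.R
        )
        traj_mean = np.empty(cfg.n_episodes)
        vfe_mean = np.empty(cfg.n_episodes)
        efe_mean = np.empty(cfg.n_episodes)
        if fast:
            _kernels.train_agent_kernel(
                env.transitions,
                env.obs_map,
                starts,
                wm.clone_map.obs_of,
                cfg.n_clones,
                n_obs,
                u_init,
                u_steps,
                _kernels.MODE_TASK if cfg.pref_mode == "task" else _kernels.MODE_EXPLORE,
                cfg.zeta,
                abs_pref,
                cfg.horizon,
                cfg.beta,
                False,  # soft look-ahead rows during training
                cfg.h0,
                cfg.gamma,
                cfg.R,
                cfg.decay_scope == "global",
                VFE_EPS,
                wm.prior.h,
                wm.posterior.h,
                traj_mean,
                vfe_mean,
                efe_mean,
            )
        else:
            _train_agent_reference(
                cfg, env, wm, abs_pref, starts, u_init, u_steps, traj_mean, vfe_mean, efe_mean
            )
        wm.meta = {
            "env": cfg.env,
            "config_hash": config_hash(cfg.to_json()),
            "episodes_trained": cfg.n_episodes,
            "agent_id": agent_id,
            "pref_mode": cfg.pref_mode,
            "zeta": cfg.zeta,
        }
        models.append(wm)
        frames.append(
            pd.DataFrame(
                {
                    "agent": agent_id,
                    "episode": np.arange(cfg.n_episodes),
                    "traj_len": traj_mean,
                    "vfe": vfe_mean,
                    "efe": efe_mean,
                    "seed": cfg.seed,
                }
            )
        )
    log = pd.concat(frames, ignore_index=True)
    w = cfg.log_window
    for col in ("traj_len", "vfe", "efe"):
        log[col + "_w"] = (
            log.groupby("agent")[col].transform(lambda s: s.rolling(w, min_periods=1).mean())
        )
    return TrainResult(config=cfg, models=models, log=log)


class _SlotRNG:
    """Generator-like shim feeding pre-drawn uniforms to the public operations."""

    def __init__(self, values):
        self._it = iter(values)

    def random(self):
        return next(self._it)


def _refresh_policy(
    cfg: RunConfig, wm: WorldModel, pi_prev: PolicyTable, abs_pref: np.ndarray
) -> PolicyTable:
    """Episode-end policy refresh (reference path).

    Task mode runs one planner iteration whose reachability starts from the
    uniform policy (seeding it from the acting policy locks the children
    sets onto already-taken transitions); exploration mode builds the
    marginal from the previous policy refresh.
    """
    if cfg.pref_mode == "task":
        uniform = PolicyTable.uniform(wm.n_beliefs, wm.n_actions)
        r = reachability(wm, uniform)
        v = propagate_values(initial_value(wm, abs_pref), r, cfg.beta, cfg.horizon)
        pref = PreferenceSpec(mode="task", abs_pref=abs_pref, lookahead=lookahead_pref(v, r))
        G = efe_matrix(wm, pref)
    else:
        G = efe_exploration_matrix(wm, pi_prev)
    return policy_from_efe(G, cfg.zeta)


def _train_agent_reference(
    cfg, env, wm, abs_pref, starts, u_init, u_steps, traj_mean, vfe_mean, efe_mean
):
    """Readable training loop built from the public step operations; consumes the
    same uniform stream as the jitted kernel."""
    S = cfg.steps_per_episode
    policy = _refresh_policy(cfg, wm, PolicyTable.uniform(wm.n_beliefs, wm.n_actions), abs_pref)
    for ep in range(cfg.n_episodes):
        e_state = int(starts[ep])
        s_env = env.obs(e_state)
        clones = wm.clone_map.clones_of(s_env)
        belief = int(
            clones[_sample_index(np.full(len(clones), 1.0 / len(clones)), u_init[ep])]
        )
        state = AgentState(belief=belief)
        lengths = []
        vfe_sum = 0.0
        efe_sum = 0.0
        for t in range(S):
            a = _sample_index(policy.pi[state.belief], u_steps[ep, t, 0])
            e_state = env.step(e_state, a)
            s_env = env.obs(e_state)
            vfe_sum += step_vfe(wm, state.belief, a, s_env)
            efe_sum += policy.G[state.belief, a]
            open_traj = state.trajectory
            matched, state = training_step(
                wm,
                state,
                a,
                s_env,
                _SlotRNG([u_steps[ep, t, 1], u_steps[ep, t, 2]]),
                decay_scope=cfg.decay_scope,
            )
            if not matched and open_traj.length > 0:
                # zero-length runs are not trajectories (no correct prediction)
                lengths.append(open_traj.length)
        if state.trajectory.steps:
            if state.trajectory.length > 0:
                lengths.append(state.trajectory.length)
            close_trajectory(state.trajectory, wm.posterior, decay_scope=cfg.decay_scope)
        traj_mean[ep] = float(np.mean(lengths)) if lengths else 0.0
        vfe_mean[ep] = vfe_sum / S
        efe_mean[ep] = efe_sum / S
        wm.prior.h[:] = wm.posterior.h
        policy = _refresh_policy(cfg, wm, policy, abs_pref)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------


def eval_predict(
    wm: WorldModel,
    env: Environment,
    rounds: int,
    steps: int,
    mode: str = "super",
    seed: int | np.random.Generator = 0,
    filter_argmax: bool = False,
) -> np.ndarray:
    """Prediction-trajectory lengths under a uniform policy.

    Each round restarts the environment (at its initial rule) and counts the
    consecutive correct observation predictions until the first failure,
    capped at ``steps``.  ``mode="single"`` tracks one sampled clone clip;
    ``mode="super"`` runs the superposition filter and counts a step as
    correct when at least one candidate's sampled successor matches.
    """
    if mode not in ("single", "super"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    uniform = PolicyTable.uniform(wm.n_beliefs, wm.n_actions)
    lengths = np.empty(rounds, dtype=np.int64)
    for rd in range(rounds):
        e_state = env.initial_state(rng)
        s_env = env.obs(e_state)
        if mode == "single":
            belief = int(rng.choice(wm.clone_map.clones_of(s_env)))
        else:
            hyp = init_hypothesis(wm.clone_map, s_env)
        length = 0
        for _ in range(steps):
            if mode == "single":
                a = _sample_index(uniform.pi[belief], rng.random())
            else:
                a = vote_action(hyp, uniform, rng)
            e_state = env.step(e_state, a)
            s_env = env.obs(e_state)
            if mode == "single":
                nxt = _sample_index(transition_prob(wm.prior.h[a, belief]), rng.random())
                ok = wm.clone_map.obs(nxt) == s_env
                if ok:
                    belief = nxt
            else:
                hyp, ok = advance(hyp, wm, a, s_env, rng, argmax=filter_argmax)
            if not ok:
                break
            length += 1
        lengths[rd] = length
    return lengths


def eval_goal(
    wm: WorldModel,
    env: Environment,
    target_obs: int,
    rounds: int,
    planner_cfg: PlannerConfig,
    seed: int = 0,
    start_states: list[int] | None = None,
    steps: int = 80,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Steps-to-target from each start state, planner policy vs. uniform.

    The policy comes from ``infer_policy`` (no environment interaction);
    belief states are estimated in superposition and actions are taken by
    candidate vote.  Rounds that never reach the target are censored at
    ``steps``.  Returns a tidy frame (start_state, round, steps, policy).
    """
    policy = infer_policy(wm, target_obs, planner_cfg)
    uniform = PolicyTable.uniform(wm.n_beliefs, wm.n_actions)
    if start_states is None:
        start_states = [e for e in range(env.n_states) if env.obs(e) != target_obs]
    rows = []
    kinds = [("planner", policy)] + ([("uniform", uniform)] if include_baseline else [])
    for kind, pol in kinds:
        rng = np.random.Generator(np.random.PCG64(seed))
        for e0 in start_states:
            for rd in range(rounds):
                e_state = e0
                s_env = env.obs(e_state)
                hyp = init_hypothesis(wm.clone_map, s_env)
                n = steps
                for t in range(1, steps + 1):
                    a = vote_action(hyp, pol, rng)
                    e_state = env.step(e_state, a)
                    s_env = env.obs(e_state)
                    if s_env == target_obs:
                        n = t
                        break
                    hyp, _ = advance(hyp, wm, a, s_env, rng)
                rows.append((kind, e0, rd, n))
    return pd.DataFrame(rows, columns=["policy", "start_state", "round", "steps"])
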
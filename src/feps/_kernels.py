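"""Numba-jitted fast path for the training loop.

These kernels replicate, loop for loop, the reference operations in
``ecm_core`` / ``world_model`` / ``policy_efe`` / ``planner``: they consume
the same pre-generated uniform stream (three slots per step: action draw,
successor draw, reset draw — the reset slot is discarded on a match) so a
fixed seed produces the same run through either path.  The equivalence is
asserted in the test suite.

Nothing here is public API; ``experiment.train`` dispatches to
``train_agent_kernel`` unless asked for the reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .policy_efe import LOG_FLOOR

__all__ = ["train_agent_kernel"]

MODE_EXPLORE = 0
MODE_TASK = 1


@njit(cache=True)
def _sample_prob_row(p, u):
    """Inverse-CDF sample from a probability row (running-sum CDF)."""
    c = 0.0
    for k in range(p.shape[0]):
        c += p[k]
        if u < c:
            return k
    return p.shape[0] - 1


@njit(cache=True)
def _sample_h_row(h, u):
    """Sample from an unnormalized non-negative row."""
    total = 0.0
    for k in range(h.shape[0]):
        total += h[k]
    c = 0.0
    for k in range(h.shape[0]):
        c += h[k] / total
        if u < c:
            return k
    return h.shape[0] - 1


@njit(cache=True)
def _uniform_clone(n_clones, u):
    inv = 1.0 / n_clones
    c = 0.0
    for j in range(n_clones):
        c += inv
        if u < c:
            return j
    return n_clones - 1


@njit(cache=True)
def _softmax_rows(G, zeta):
    nb, na = G.shape
    pi = np.empty((nb, na))
    for b in range(nb):
        m = zeta * G[b, 0]
        for a in range(1, na):
            z = zeta * G[b, a]
            if z > m:
                m = z
        s = 0.0
        for a in range(na):
            pi[b, a] = np.exp(zeta * G[b, a] - m)
            s += pi[b, a]
        for a in range(na):
            pi[b, a] /= s
    return pi


@njit(cache=True)
def _trans_probs(h):
    na, nb = h.shape[0], h.shape[1]
    P = np.empty_like(h)
    for a in range(na):
        for b in range(nb):
            s = 0.0
            for j in range(nb):
                s += h[a, b, j]
            for j in range(nb):
                P[a, b, j] = h[a, b, j] / s
    return P


@njit(cache=True)
def _explore_G(P, pi):
    """Information-gain EFE: KL[p(B'|b,a) || sum_a' pi(a'|b) p(B'|b,a')]."""
    na, nb = P.shape[0], P.shape[1]
    G = np.zeros((nb, na))
    for b in range(nb):
        marg = np.zeros(nb)
        for a in range(na):
            w = pi[b, a]
            for j in range(nb):
                marg[j] += w * P[a, b, j]
        for a in range(na):
            g = 0.0
            for j in range(nb):
                p = P[a, b, j]
                if p > 0.0:
                    m = marg[j]
                    if m < LOG_FLOOR:
                        m = LOG_FLOOR
                    g += p * np.log(p / m)
            G[b, a] = g
    return G


@njit(cache=True)
def _task_refresh(P, pi_prev, abs_pref, obs_of, horizon, beta, pref_argmax):
    """One planner iteration: reachability -> values -> look-ahead pref ->
    task EFE matrix (mirrors planner.infer_policy with k_pref=1)."""
    na, nb = P.shape[0], P.shape[1]
    r = np.zeros((nb, nb))
    for b in range(nb):
        for a in range(na):
            w = pi_prev[b, a]
            for j in range(nb):
                r[b, j] += w * P[a, b, j]
    v = np.empty(nb)
    for b in range(nb):
        v[b] = abs_pref[obs_of[b]]
    for n in range(1, horizon + 1):
        disc = beta ** (n - 1)
        vn = np.empty(nb)
        for b in range(nb):
            best = 0.0
            for j in range(nb):
                c = r[b, j] * v[j]
                if c > best:
                    best = c
            cand = disc * best
            vn[b] = v[b] if v[b] >= cand else cand
        v = vn
    pref = np.zeros((nb, nb))
    for b in range(nb):
        mean = 0.0
        for j in range(nb):
            mean += r[b, j]
        mean /= nb
        total = 0.0
        nch = 0
        for j in range(nb):
            if r[b, j] > mean:
                nch += 1
                total += v[j]
        if nch == 0:
            for j in range(nb):
                pref[b, j] = 1.0 / nb
        elif total <= 0.0:
            for j in range(nb):
                if r[b, j] > mean:
                    pref[b, j] = 1.0 / nch
        else:
            for j in range(nb):
                if r[b, j] > mean:
                    pref[b, j] = v[j] / total
        if pref_argmax:
            best_j = 0
            best_v = pref[b, 0]
            for j in range(1, nb):
                if pref[b, j] > best_v:
                    best_v = pref[b, j]
                    best_j = j
            for j in range(nb):
                pref[b, j] = 0.0
            pref[b, best_j] = 1.0
    look_floor = 1.0 / nb
    G = np.zeros((nb, na))
    for b in range(nb):
        for a in range(na):
            g = 0.0
            for j in range(nb):
                p = P[a, b, j]
                if p > 0.0:
                    g += p * np.log(p)
                    pa = abs_pref[obs_of[j]]
                    if pa < LOG_FLOOR:
                        pa = LOG_FLOOR
                    pl = pref[b, j]
                    if pl < look_floor:
                        pl = look_floor
                    g -= p * (np.log(pa) + np.log(pl))
            G[b, a] = g
    return G


@njit(cache=True)
def _step_vfe(hq, hp, obs_of, s_env, log_1me, log_eps_term):
    """KL[posterior row || prior row] + smoothed-emission surprise."""
    nb = hq.shape[0]
    sq = 0.0
    sp = 0.0
    for j in range(nb):
        sq += hq[j]
        sp += hp[j]
    kl = 0.0
    match = 0.0
    for j in range(nb):
        q = hq[j] / sq
        if q > 0.0:
            kl += q * np.log(q / (hp[j] / sp))
        if obs_of[j] == s_env:
            match += hq[j] / sq
    return kl - (match * log_1me + (1.0 - match) * log_eps_term)


@njit(cache=True)
def _close_trajectory(h_post, ea, eb, ec, epos, n_edges, L, h0, gamma, R, global_decay):
    """Confidence-weighted rewards at trajectory close; f = L - first_use."""
    if global_decay:
        na, nb = h_post.shape[0], h_post.shape[1]
        for a in range(na):
            for b in range(nb):
                for j in range(nb):
                    h_post[a, b, j] -= gamma * (h_post[a, b, j] - h0)
        for i in range(n_edges):
            f = L - epos[i]
            h_post[ea[i], eb[i], ec[i]] += f * R
    else:
        for i in range(n_edges):
            f = L - epos[i]
            h = h_post[ea[i], eb[i], ec[i]]
            h_post[ea[i], eb[i], ec[i]] = h - gamma * (h - h0) + f * R


@njit(cache=True)
def train_agent_kernel(
    env_T,
    env_obs,
    start_states,
    obs_of,
    n_clones,
    n_obs,
    u_init,
    u_steps,
    mode,
    zeta,
    abs_pref,
    horizon,
    beta,
    pref_argmax,
    h0,
    gamma,
    R,
    global_decay,
    eps,
    h_prior,
    h_post,
    traj_mean,
    vfe_mean,
    efe_mean,
):
    """Full training run of one agent; mutates the h-tables and log arrays.

    Per episode: reset belief to a random clone of the initial observation,
    run the prediction/confidence loop for every step, close the open
    trajectory at episode end (with rewards), sync prior <- posterior and
    refresh the policy (exploration or task EFE from the previous policy).
    """
    E = u_steps.shape[0]
    S = u_steps.shape[1]
    na = h_prior.shape[0]
    nb = h_prior.shape[1]
    log_1me = np.log1p(-eps)
    log_eps_term = np.log(eps / (n_obs - 1))

    pi_uniform = np.full((nb, na), 1.0 / na)
    pi = pi_uniform
    P = _trans_probs(h_prior)
    if mode == MODE_EXPLORE:
        G = _explore_G(P, pi)
    else:
        G = _task_refresh(P, pi_uniform, abs_pref, obs_of, horizon, beta, pref_argmax)
    pi = _softmax_rows(G, zeta)

    max_edges = S + 1
    ea = np.empty(max_edges, np.int64)
    eb = np.empty(max_edges, np.int64)
    ec = np.empty(max_edges, np.int64)
    epos = np.empty(max_edges, np.int64)

    for ep in range(E):
        e_state = start_states[ep]
        s_env = env_obs[e_state]
        belief = n_clones * s_env + _uniform_clone(n_clones, u_init[ep])
        n_edges = 0
        L = 0
        n_traj = 0
        len_sum = 0.0
        vfe_sum = 0.0
        efe_sum = 0.0
        for t in range(S):
            a = _sample_prob_row(pi[belief], u_steps[ep, t, 0])
            b_next = _sample_h_row(h_prior[a, belief], u_steps[ep, t, 1])
            s_hat = obs_of[b_next]
            e_next = env_T[e_state, a]
            s_env = env_obs[e_next]
            vfe_sum += _step_vfe(
                h_post[a, belief], h_prior[a, belief], obs_of, s_env, log_1me, log_eps_term
            )
            efe_sum += G[belief, a]
            found = False
            for i in range(n_edges):
                if ea[i] == a and eb[i] == belief and ec[i] == b_next:
                    found = True
                    break
            if not found:
                ea[n_edges] = a
                eb[n_edges] = belief
                ec[n_edges] = b_next
                epos[n_edges] = L
                n_edges += 1
            if s_hat == s_env:
                L += 1
                belief = b_next
            else:
                _close_trajectory(h_post, ea, eb, ec, epos, n_edges, L, h0, gamma, R, global_decay)
                # a run with no correct prediction is not a trajectory and
                # does not enter the length statistics
                if L > 0:
                    n_traj += 1
                    len_sum += L
                n_edges = 0
                L = 0
                belief = n_clones * s_env + _uniform_clone(n_clones, u_steps[ep, t, 2])
            e_state = e_next
        if n_edges > 0:
            _close_trajectory(h_post, ea, eb, ec, epos, n_edges, L, h0, gamma, R, global_decay)
            if L > 0:
                n_traj += 1
                len_sum += L
        traj_mean[ep] = len_sum / n_traj if n_traj > 0 else 0.0
        vfe_mean[ep] = vfe_sum / S
        efe_mean[ep] = efe_sum / S
        for a in range(na):
            for b in range(nb):
                for j in range(nb):
                    h_prior[a, b, j] = h_post[a, b, j]
        P = _trans_probs(h_prior)
        if mode == MODE_EXPLORE:
            G = _explore_G(P, pi)
        else:
            G = _task_refresh(P, pi_uniform, abs_pref, obs_of, horizon, beta, pref_argmax)
        pi = _softmax_rows(G, zeta)
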
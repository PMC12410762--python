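"""Superposition belief estimation: initialization, action voting,
candidate advancement/elimination and equivalence with an exact support
filter."""

import numpy as np
import pytest

from feps import (
    Hypothesis,
    PolicyTable,
    WorldModel,
    advance,
    init_hypothesis,
    make_env,
    random_pomdp,
    vote_action,
)
# clone <-> hidden-state mappings of the hand-built exact models
TIMED_CLONE_OF_STATE = {0: 0, 1: 4, 2: 5, 3: 2}


def grid_clone_of_cell():
    env = make_env("grid3")
    cells_of_obs = {s: [e for e in range(9) if env.obs(e) == s] for s in range(4)}
    return {cells[j]: s * 3 + j for s, cells in cells_of_obs.items() for j in range(len(cells))}


class TestInitHypothesis:
    def test_all_clones_included(self, perfect_grid):
        h = init_hypothesis(perfect_grid.clone_map, 0)
        assert h.candidates == [0, 1, 2]
        assert all(perfect_grid.clone_map.obs(c) == 0 for c in h.candidates)

    def test_single_clone_degenerates_to_tracking(self):
        wm = WorldModel.fresh(4, 1, 2)
        h = init_hypothesis(wm.clone_map, 2)
        assert h.candidates == [2]

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            Hypothesis(candidates=[])


class TestVoteAction:
    def test_shared_deterministic_row(self, rng):
        pi = np.zeros((4, 3))
        pi[:, 1] = 1.0
        policy = PolicyTable(G=np.log(np.maximum(pi, 1e-300)), zeta=1.0)
        h = Hypothesis(candidates=[0, 1, 2])
        assert all(vote_action(h, policy, rng) == 1 for _ in range(30))

    def test_opposite_deterministic_rows_split_evenly(self, rng):
        G = np.array([[0.0, -50.0], [-50.0, 0.0]])
        policy = PolicyTable(G=G, zeta=1.0)  # cand 0 -> action 0, cand 1 -> action 1
        h = Hypothesis(candidates=[0, 1])
        n = 4000
        freq = np.mean([vote_action(h, policy, rng) for _ in range(n)])
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_single_candidate_follows_policy_row(self, rng):
        pi_row = np.array([0.7, 0.2, 0.1])
        policy = PolicyTable(G=np.log(pi_row)[None, :], zeta=1.0)
        h = Hypothesis(candidates=[0])
        n = 5000
        counts = np.bincount([vote_action(h, policy, rng) for _ in range(n)], minlength=3) / n
        assert np.all(np.abs(counts - pi_row) < 3 * np.sqrt(pi_row * (1 - pi_row) / n) + 1e-9)

    def test_exact_mixture_variant(self, rng):
        pi = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        policy = PolicyTable(G=np.log(np.maximum(pi, 1e-300)), zeta=1.0)
        h = Hypothesis(candidates=[0, 1, 2])
        n = 3000
        freq = np.mean([vote_action(h, policy, rng, exact_mixture=True) for _ in range(n)])
        # exact mixture: action 1 with probability 1/3
        assert abs(freq - 1 / 3) < 3 * np.sqrt(2 / 9 / n) + 0.01


class TestAdvance:
    def test_disambiguation_on_perfect_grid(self, perfect_grid, rng):
        """Starting ambiguous among the three smell-0 cells, a short action
        sequence narrows the hypothesis to the single true clone."""
        env = make_env("grid3")
        clone_of = grid_clone_of_cell()
        e = 0  # lower-left corner
        h = init_hypothesis(perfect_grid.clone_map, env.obs(e))
        assert len(h.candidates) == 3
        for a in (2, 1):  # up then left: distinguishes corner from its neighbours
            e = env.step(e, a)
            h, ok = advance(h, perfect_grid, a, env.obs(e), rng, argmax=True)
            assert ok
        assert h.candidates == [clone_of[e]]

    def test_wrong_model_resets_to_observation_clones(self, rng):
        wm = WorldModel.fresh(3, 2, 1)
        wm.prior.h[0, :, :] = 0.0
        wm.prior.h[0, :, 0] = 1.0  # every candidate predicts observation 0
        h = Hypothesis(candidates=[0, 1])
        h2, ok = advance(h, wm, 0, 2, rng)
        assert not ok
        assert h2.candidates == [4, 5]  # all clones of the observed state

    def test_duplicates_merge(self, rng):
        wm = WorldModel.fresh(2, 2, 1)
        wm.prior.h[0, :, :] = 0.0
        wm.prior.h[0, :, 1] = 1.0  # all candidates map to clip 1
        h = Hypothesis(candidates=[0, 1, 2, 3])
        h2, ok = advance(h, wm, 0, 0, rng)
        assert ok
        assert h2.candidates == [1]

    def test_monotone_shrink_between_resets(self, perfect_grid, rng):
        env = make_env("grid3")
        e = int(rng.integers(9))
        h = init_hypothesis(perfect_grid.clone_map, env.obs(e))
        size = len(h.candidates)
        for _ in range(30):
            a = int(rng.integers(4))
            e = env.step(e, a)
            h, ok = advance(h, perfect_grid, a, env.obs(e), rng, argmax=True)
            if ok:
                assert len(h.candidates) <= size
            size = len(h.candidates)

    @pytest.mark.parametrize("env_name", ["timed", "grid3"])
    def test_true_state_never_eliminated(self, env_name, perfect_timed, perfect_grid, rng):
        """Soundness: with an exact model and argmax advancement the clone
        of the true hidden state always survives elimination."""
        env = make_env(env_name)
        if env_name == "timed":
            wm, clone_of = perfect_timed, TIMED_CLONE_OF_STATE
        else:
            wm, clone_of = perfect_grid, grid_clone_of_cell()
        for e0 in range(env.n_states):
            e = e0
            h = init_hypothesis(wm.clone_map, env.obs(e))
            for _ in range(20):
                a = int(rng.integers(env.n_actions))
                e = env.step(e, a)
                h, ok = advance(h, wm, a, env.obs(e), rng, argmax=True)
                assert ok
                assert clone_of[e] in h.candidates

    def test_matches_exact_support_filter(self, rng):
        """On random deterministic POMDPs (<= 12 states) the argmax-advanced
        candidate set equals the support of an exact Bayes filter with
        deterministic emission and argmax-pruned transitions."""
        for seed in range(8):
            env = random_pomdp(n_states=6 + seed % 5, n_obs=3, n_actions=2, seed=seed)
            # exact copy of the environment, one clone per aliased state
            wm = WorldModel.fresh(env.n_obs, max(
                np.bincount(env.obs_map, minlength=env.n_obs).max(), 1
            ), env.n_actions, h0=1e-9)
            clone_of = {}
            counter = {s: 0 for s in range(env.n_obs)}
            for e in range(env.n_states):
                s = env.obs(e)
                clone_of[e] = s * wm.clone_map.n_clones + counter[s]
                counter[s] += 1
            for e in range(env.n_states):
                for a in range(env.n_actions):
                    wm.prior.h[a, clone_of[e], :] = 1e-9
                    wm.prior.h[a, clone_of[e], clone_of[int(env.transitions[e, a])]] = 1.0
            # boolean argmax transition matrices (independent oracle path)
            nb = wm.n_beliefs
            M = np.zeros((env.n_actions, nb, nb), dtype=bool)
            for a in range(env.n_actions):
                M[a, np.arange(nb), wm.transition_matrix(a).argmax(axis=1)] = True
            obs_of = wm.clone_map.obs_of
            e = env.initial_state(rng)
            h = init_hypothesis(wm.clone_map, env.obs(e))
            support = np.zeros(nb, dtype=bool)
            support[wm.clone_map.clones_of(env.obs(e))] = True
            for _ in range(15):
                a = int(rng.integers(env.n_actions))
                e = env.step(e, a)
                s_env = env.obs(e)
                h, ok = advance(h, wm, a, s_env, rng, argmax=True)
                new_support = (support @ M[a]) & (obs_of == s_env)
                if not new_support.any():
                    new_support = obs_of == s_env  # reset rule
                support = new_support
                assert sorted(np.flatnonzero(support)) == h.candidates

    def test_termination_within_distinguishing_bound(self, perfect_grid, rng):
        """Every ambiguous pair of grid cells is separated by its shortest
        distinguishing action sequence (exhaustively enumerated), and the
        filter eliminates the impostor within that many steps."""
        env = make_env("grid3")
        clone_of = grid_clone_of_cell()
        from collections import deque

        def shortest_distinguishing(e1, e2):
            seen = {(e1, e2)}
            q = deque([(e1, e2, [])])
            while q:
                x, y, seq = q.popleft()
                for a in range(4):
                    x2, y2 = env.step(x, a), env.step(y, a)
                    if env.obs(x2) != env.obs(y2):
                        return seq + [a]
                    if x2 != y2 and (x2, y2) not in seen:
                        seen.add((x2, y2))
                        q.append((x2, y2, seq + [a]))
            return None

        bound = 0
        for e1 in range(9):
            for e2 in range(e1 + 1, 9):
                if env.obs(e1) != env.obs(e2):
                    continue
                seq = shortest_distinguishing(e1, e2)
                assert seq is not None  # the grid is fully disambiguable
                bound = max(bound, len(seq))
                # drive the environment from e1; the impostor e2's clone dies
                e = e1
                h = Hypothesis(candidates=[clone_of[e1], clone_of[e2]])
                for a in seq:
                    e = env.step(e, a)
                    h, ok = advance(h, perfect_grid, a, env.obs(e), rng, argmax=True)
                assert h.candidates == [clone_of[e]]
        assert bound <= 9  # enumerated ambiguity horizon of the grid
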
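"""Agent primitives: action selection, update rules, replay, architectures."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srgrid.agents import (
    AgentParams, ExperienceBuffer, agent_step, draw_replay_samples,
    dynaq_update, epsilon_greedy, make_agent, onestep_lookahead_q,
    srmb_policy_update, srmb_transition_row,
)
from srgrid.gridworld import (
    COLLECT, E, N, S, TERMINAL, W, Transition, parse_grid_map,
)
from srgrid.sr_core import h_online_update, sa_index, td_error, \
    weight_update_td
from srgrid.analysis import value_iteration

GAMMA = 0.95


class TestEpsilonGreedy:
    def test_single_action_forced(self):
        assert epsilon_greedy([1.0], 0.1, random.Random(0)) == 0

    def test_all_zero_row_is_uniform(self):
        rng = random.Random(2)
        counts = [0] * 4
        for _ in range(20000):
            counts[epsilon_greedy([0.0] * 4, 0.1, rng)] += 1
        for c in counts:
            assert abs(c / 20000 - 0.25) < 0.02

    def test_best_action_probability(self):
        # distinct max among 4 actions: P(best) = 0.9 + 0.1/4 = 0.925,
        # checked by Monte-Carlo frequency within 3 sigma at n = 1e5
        rng = random.Random(3)
        n = 100_000
        hits = sum(
            epsilon_greedy([0.0, 3.0, 1.0, 2.0], 0.1, rng) == 1
            for _ in range(n))
        sigma = (0.925 * 0.075 / n) ** 0.5
        assert abs(hits / n - 0.925) <= 3 * sigma

    def test_empty_row_is_error(self):
        with pytest.raises(ValueError):
            epsilon_greedy([], 0.1, random.Random(0))

    @given(k=st.integers(1, 5), eps=st.floats(0, 1),
           seed=st.integers(0, 10 ** 6))
    @settings(derandomize=True, max_examples=50)
    def test_returns_an_available_action(self, k, eps, seed):
        rng = random.Random(seed)
        actions = tuple(range(10, 10 + k))
        q = [rng.random() for _ in range(k)]
        assert epsilon_greedy(q, eps, rng, actions) in actions


class TestOneStepLookahead:
    def test_copies_neighbor_values(self):
        world = parse_grid_map("...\n...\n...")
        V = np.arange(9, dtype=float)
        q, acts = onestep_lookahead_q(V, world, world.state((1, 1)))
        assert acts == (N, E, S, W)
        assert q == [V[world.state((1, 0))], V[world.state((2, 1))],
                     V[world.state((1, 2))], V[world.state((0, 1))]]

    def test_zero_values_give_zero_row(self):
        world = parse_grid_map("...\n...\n...")
        q, _ = onestep_lookahead_q(np.zeros(9), world, 4)
        assert q == [0.0, 0.0, 0.0, 0.0]

    def test_collect_maps_to_terminal_continuation(self):
        world = parse_grid_map("S.R").set_reward("R", 10.0)
        q, acts = onestep_lookahead_q(np.full(3, 7.0), world,
                                      world.state("R"))
        assert acts == (COLLECT,) and q == [0.0]


class TestSRMBPrimitives:
    def test_policy_delta_rule_arithmetic(self):
        row = srmb_policy_update(np.full(4, 0.25), 0, 0.1)
        np.testing.assert_allclose(row, [0.325, 0.225, 0.225, 0.225])

    def test_alpha_one_gives_onehot(self):
        row = srmb_policy_update(np.full(4, 0.25), 2, 1.0)
        np.testing.assert_allclose(row, [0, 0, 1.0, 0])

    @given(choices=st.lists(st.integers(0, 3), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_rows_always_sum_to_one(self, choices):
        row = np.full(4, 0.25)
        for c in choices:
            srmb_policy_update(row, c, 0.1)
        assert row.sum() == pytest.approx(1.0)
        assert np.all(row >= 0)

    def test_repeated_choice_converges_geometrically(self):
        row = np.full(4, 0.25)
        for _ in range(200):
            srmb_policy_update(row, 1, 0.1)
        assert row[1] == pytest.approx(1.0, abs=1e-6)

    def test_transition_row_uniform_four_neighbors(self):
        physics = {N: 1, E: 2, S: 3, W: 4}
        row = srmb_transition_row(np.full(4, 0.25), (N, E, S, W), physics, 6)
        np.testing.assert_allclose(row[1:5], 0.25)

    def test_transition_row_renormalizes_after_block(self):
        physics = {N: 1, E: 2, S: 3, W: 4}
        row = srmb_transition_row(np.full(4, 0.25), (N, S, W), physics, 6)
        np.testing.assert_allclose(row[[1, 3, 4]], 1 / 3)
        assert row[2] == 0.0

    def test_collect_only_state_gives_zero_row(self):
        row = srmb_transition_row(np.full(4, 0.25), (COLLECT,), {}, 6)
        np.testing.assert_allclose(row, 0.0)


class TestDynaQUpdate:
    def test_terminal_reward_backup(self):
        Q = np.zeros((2, 5))
        dynaq_update(Q, (0, COLLECT, 10.0, TERMINAL), 0.3, GAMMA, ())
        assert Q[0, COLLECT] == pytest.approx(3.0)

    def test_consistent_estimate_unchanged(self):
        Q = np.zeros((2, 5))
        Q[0, E], Q[1, E] = GAMMA * 4.0, 4.0
        dynaq_update(Q, (0, E, 0.0, 1), 0.3, GAMMA, (E,))
        assert Q[0, E] == pytest.approx(GAMMA * 4.0)

    def test_chain_sweeps_reach_value_iteration_oracle(self):
        world = parse_grid_map("S.R").set_reward("R", 10.0)
        s0, s1, s2 = world.state("S"), world.state((1, 0)), world.state("R")
        samples = [(s0, E, 0.0, s1), (s1, E, 0.0, s2),
                   (s2, COLLECT, 10.0, TERMINAL)]
        Q = np.zeros((3, 5))
        for _ in range(200):
            for smp in samples:
                nxt = () if smp[3] == TERMINAL \
                    else world.available_actions(smp[3])
                dynaq_update(Q, smp, 0.3, GAMMA, nxt)
        V = value_iteration(world, GAMMA)
        assert Q[s2, COLLECT] == pytest.approx(10.0, abs=1e-4)
        assert Q[s1, E] == pytest.approx(V[s1], abs=1e-4)
        assert Q[s0, E] == pytest.approx(V[s0], abs=1e-4)


class TestReplayDraws:
    def _buffer(self, samples):
        buf = ExperienceBuffer()
        for smp in samples:
            buf.append(Transition(*smp))
        return buf

    def test_single_sample_always_returned(self):
        buf = self._buffer([(0, E, 0.0, 1)])
        out = draw_replay_samples(buf, 5, "per_step", random.Random(0))
        assert len(out) == 5 and all(t.s == 0 for t in out)

    def test_recency_ratio_matches_exponential(self):
        # two samples of the same state-action: P(recent)/P(older) = e^{1/5}
        buf = self._buffer([(0, E, 0.0, 1), (0, E, 0.0, 2)])
        rng = random.Random(4)
        n = 100_000
        p = np.exp(0.2) / (1 + np.exp(0.2))
        for scheme in ("per_step", "post_change"):
            hits = sum(t.s_next == 2 for t in
                       draw_replay_samples(buf, n, scheme, rng))
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(hits / n - p) <= 3 * sigma

    def test_uniform_over_state_actions_ignores_visit_counts(self):
        samples = [(0, E, 0.0, 1)] * 20 + [(1, W, 0.0, 0)]
        buf = self._buffer(samples)
        rng = random.Random(5)
        n = 100_000
        hits = sum(t.s == 1 for t in
                   draw_replay_samples(buf, n, "post_change", rng))
        sigma = (0.25 / n) ** 0.5
        assert abs(hits / n - 0.5) <= 3 * sigma

    def test_empty_buffer_returns_empty(self):
        assert draw_replay_samples(ExperienceBuffer(), 3, "per_step",
                                   random.Random(0)) == []

    def test_buffer_stamps_strictly_increase(self):
        buf = self._buffer([(0, E, 0.0, 1), (1, E, 0.0, 0), (0, E, 0.0, 1)])
        assert buf.by_sa[(0, E)] == [0, 2]
        assert len(buf) == 3


class TestArchitectures:
    @pytest.fixture
    def world(self):
        return parse_grid_map("S...\n....\n...R").add_goal("R", 0.0)

    def test_sr_td_no_reward_leaves_weights_zero(self, world):
        agent = make_agent("sr_td", world)
        rng = random.Random(0)
        agent.place(world, world.state("S"), rng)
        for _ in range(500):
            agent_step(agent, world, agent.s if agent.s is not None
                       else world.state("S"), rng)
        assert not agent.w.any()
        assert agent.M.sum() > world.n_states  # occupancies drifted off I

    def test_dynaq_first_collect_updates_only_that_entry(self, world):
        rewarded = world.set_reward("R", 10.0)
        params = AgentParams(n_replay_per_step=0, k_post_change=0)
        agent = make_agent("dyna_q", rewarded, params)
        rng = random.Random(1)
        agent.place(rewarded, rewarded.state("R"), rng)
        agent.step(rewarded, rng)
        nz = np.nonzero(agent.Q)
        assert list(zip(*nz)) == [(rewarded.state("R"), COLLECT)]

    def test_sr_dyna_without_replay_is_online_sarsa_sr(self, world):
        """SR-Dyna with replay disabled must equal a plain online SARSA-SR
        learner: rebuilding H and w from the experienced state-action
        sequence with the core update rules reproduces them exactly."""
        rewarded = world.set_reward("R", 10.0)
        params = AgentParams(n_replay_per_step=0, k_post_change=0)
        agent = make_agent("sr_dyna", rewarded, params)
        rng = random.Random(2)
        start = rewarded.state("S")
        episodes: list[list] = []
        cur: list = []
        agent.place(rewarded, start, rng)
        # stop exactly at an episode boundary so every recorded transition's
        # successor action is the next transition actually executed
        for _ in range(5000):
            tr = agent.step(rewarded, rng)
            cur.append(tr)
            if tr.s_next == TERMINAL:
                episodes.append(cur)
                cur = []
                if len(episodes) == 5:
                    break
                agent.place(rewarded, start, rng)
        assert len(episodes) == 5
        # independent reconstruction (SARSA-SR over the same experience)
        n_sa = rewarded.n_states * 5
        H = np.eye(n_sa)
        w = np.zeros(n_sa)
        for ep in episodes:
            for i, tr in enumerate(ep):
                sa = sa_index(tr.s, tr.a)
                if tr.s_next == TERMINAL:
                    sa_next = TERMINAL
                    cont = 0.0
                else:
                    nxt = ep[i + 1]
                    sa_next = sa_index(nxt.s, nxt.a)
                    cont = float(H[sa_next] @ w)
                delta = td_error(tr.r, GAMMA, cont, float(H[sa] @ w))
                if delta != 0.0 or w.any():
                    weight_update_td(w, H[sa].copy(), delta, 0.3,
                                     "normalized")
                h_online_update(H, sa, sa_next, 0.3, GAMMA)
        np.testing.assert_array_equal(agent.H, H)
        np.testing.assert_array_equal(agent.w, w)

    def test_estimates_stay_finite_across_parameter_grid(self, world):
        rewarded = world.set_reward("R", 10.0)
        rng = random.Random(3)
        for alpha in (0.1, 0.9):
            for name in ("onestep_td", "sr_td", "sr_dyna", "dyna_q"):
                params = AgentParams(alpha_w=alpha, alpha_sr=alpha,
                                     alpha_q=alpha, n_replay_per_step=5,
                                     k_post_change=0)
                agent = make_agent(name, rewarded, params)
                agent.place(rewarded, rewarded.state("S"), rng)
                for _ in range(300):
                    if agent.s is None:
                        agent.place(rewarded, rewarded.state("S"), rng)
                    agent.step(rewarded, rng)
                assert np.isfinite(agent.value_table(rewarded)).all()

    def test_srmb_believed_rows_substochastic(self, world):
        agent = make_agent("sr_mb", world)
        rng = random.Random(4)
        agent.place(world, world.state("S"), rng)
        for _ in range(300):
            if agent.s is None:
                agent.place(world, world.state("S"), rng)
            agent.step(world, rng)
        assert np.allclose(agent.pi.sum(axis=1), 1.0)
        T = agent.transition_matrix()
        sums = T.sum(axis=1)
        assert np.all(sums <= 1.0 + 1e-12)
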
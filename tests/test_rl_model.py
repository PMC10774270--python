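import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seqvalue as sv
from seqvalue.rl_model import Q_INIT
from seqvalue.synthetic_data import WORKED_EXAMPLE_CHOICES, WORKED_EXAMPLE_REWARDS


from _oracles import oracle_sequence

WX_PARAMS = sv.AgentParams(0.25, 0.35, 0.45, 0.6, 2.0, 3.0, 4.0)


class TestSoftmax:
    @pytest.mark.parametrize("pair,beta,expected", [
        ((0.5, 0.5), 7.3, (0.5, 0.5)),
        ((0.9, 0.1), 0.0, (0.5, 0.5)),
        ((0.8, 0.2), 3.0, (1 / (1 + np.exp(-1.8)), None)),
    ])
    def test_values(self, pair, beta, expected):
        p = sv.softmax_policy(pair, beta)
        assert p[0] == pytest.approx(expected[0], abs=1e-10)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_overflow_safe_and_normalized(self):
        for v in ([700.0, 0.0], [0.0, 700.0], [1e3, 1e3]):
            p = sv.softmax_policy(tuple(v), 1.0)
            assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            sv.softmax_policy((0.5, 0.4), -1.0)


class TestPredictionErrors:
    @pytest.mark.parametrize("vals,r,expected", [
        ((0.5, 0.5, 0.5), 1, (0.0, 0.0, 0.5)),
        ((0.0, 0.0, 0.0), 0, (0.0, 0.0, 0.0)),
        ((0.2, 0.6, 0.4), 1, (0.4, -0.2, 0.6)),
    ])
    def test_arithmetic(self, vals, r, expected):
        q = sv.QTable(0.0)
        q.q[sv.QTable.index(1, 0, 0)] = vals[0]
        q.q[sv.QTable.index(2, 0, 0)] = vals[1]
        q.q[sv.QTable.index(3, 0, 0)] = vals[2]
        pe = sv.compute_prediction_errors(q, (0, 0, 0), r)
        assert (pe.pe1, pe.pe2, pe.pe3) == pytest.approx(expected)


class TestUpdate:
    def test_worked_example_values(self):
        q = sv.QTable(0.5)
        p = sv.AgentParams(0.1, 0.2, 0.3, 0.5, 1, 1, 1)
        out = sv.update_values(q, (0, 0, 0), 1, p)
        assert out.chosen_values(0, 0, 0) == pytest.approx((0.5125, 0.55, 0.65))

    def test_zero_learning_rates_freeze_table(self):
        q = sv.QTable(0.37)
        p = sv.AgentParams(0, 0, 0, 0.5, 1, 1, 1)
        out = sv.update_values(q, (1, 0, 1), 1, p)
        np.testing.assert_array_equal(out.q, q.q)

    def test_lambda_one_telescopes_to_terminal_reward(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            q = sv.QTable(rng.random(14))
            a1 = rng.random()
            p = sv.AgentParams(a1, rng.random(), rng.random(), 1.0, 1, 1, 1)
            r = int(rng.random() < 0.5)
            v1 = q.value(1, 0, 0)
            out = sv.update_values(q, (0, 0, 0), r, p)
            assert out.value(1, 0, 0) == pytest.approx(v1 + a1 * (r - v1), abs=1e-12)

    def test_lambda_zero_equals_one_step_td(self, worked_example):
        """With no eligibility trace each stage is an independent TD learner."""
        p = sv.AgentParams(0.3, 0.4, 0.5, 0.0, 2, 2, 2)
        # independent one-step TD oracle per stage
        td = {1: {(0, a): Q_INIT for a in (0, 1)},
              2: {(s, a): Q_INIT for s in range(2) for a in (0, 1)},
              3: {(s, a): Q_INIT for s in range(4) for a in (0, 1)}}
        alphas = {1: 0.3, 2: 0.4, 3: 0.5}
        q = sv.QTable(Q_INIT)
        for (c1, c2, c3), r in zip(WORKED_EXAMPLE_CHOICES, WORKED_EXAMPLE_REWARDS):
            s2, s3 = c1, 2 * c1 + c2
            targets = {1: td[2][(s2, c2)], 2: td[3][(s3, c3)], 3: r}
            keys = {1: (0, c1), 2: (s2, c2), 3: (s3, c3)}
            for k in (1, 2, 3):
                td[k][keys[k]] += alphas[k] * (targets[k] - td[k][keys[k]])
            q = sv.update_values(q, (c1, c2, c3), r, p)
        for k in (1, 2, 3):
            for key, val in td[k].items():
                assert q.value(k, *key) == pytest.approx(val, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_containment_in_unit_interval(self, data):
        """Values initialized in [0,1] can never leave it (convexity)."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
        q = sv.QTable(rng.random(14))
        p = sv.AgentParams(*rng.random(4), *(20 * rng.random(3)))
        choices = tuple(rng.integers(0, 2, 3))
        r = int(rng.random() < 0.5)
        out = sv.update_values(q, choices, r, p)
        assert out.q.min() >= 0.0 and out.q.max() <= 1.0


class TestLikelihood:
    def test_beta_zero_gives_log_half_per_stage(self):
        q = sv.QTable(0.8)
        p = sv.AgentParams(0.1, 0.1, 0.1, 0.5, 0, 0, 0)
        assert sv.trial_log_likelihood(q, (1, 1, 0), p) == pytest.approx(3 * np.log(0.5))

    def test_deterministic_limit_approaches_zero(self):
        q = sv.QTable(0.5)
        q.q[0] = 0.9  # action 0 clearly best at stage 1
        lls = [sv.trial_log_likelihood(q, (0, 0, 0),
                                       sv.AgentParams(0, 0, 0, 0, b, 0, 0))
               for b in (1, 10, 100)]
        # the two beta=0 stages pin the total at 2*log(0.5); the chosen
        # argmax stage contributes -> 0 from below as beta grows
        assert lls[0] < lls[1] < lls[2] < 0
        assert lls[2] == pytest.approx(2 * np.log(0.5), abs=0.02)

    def test_trial_equals_sum_of_softmax_logs(self):
        rng = np.random.default_rng(8)
        q = sv.QTable(rng.random(14))
        p = sv.AgentParams(0.2, 0.2, 0.2, 0.5, 1.5, 2.5, 3.5)
        c = (1, 0, 1)
        s2, s3 = 1, 2
        expected = (np.log(sv.softmax_policy((q.value(1, 0, 0), q.value(1, 0, 1)), 1.5)[1])
                    + np.log(sv.softmax_policy((q.value(2, s2, 0), q.value(2, s2, 1)), 2.5)[0])
                    + np.log(sv.softmax_policy((q.value(3, s3, 0), q.value(3, s3, 1)), 3.5)[1]))
        assert sv.trial_log_likelihood(q, c, p) == pytest.approx(expected, abs=1e-12)

    def test_sequence_matches_straight_line_oracle(self, worked_example):
        ours = sv.sequence_log_likelihood(worked_example, WX_PARAMS)
        oracle, _ = oracle_sequence(WORKED_EXAMPLE_CHOICES, WORKED_EXAMPLE_REWARDS,
                                    WX_PARAMS)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_replay_matches_oracle_table(self, worked_example):
        qvals = sv.replay_q_values(worked_example, WX_PARAMS)
        _, q_final = oracle_sequence(WORKED_EXAMPLE_CHOICES, WORKED_EXAMPLE_REWARDS,
                                     WX_PARAMS)
        # replay the last trial's offered pairs against the oracle's table
        # one step before the end
        _, q_prev = oracle_sequence(WORKED_EXAMPLE_CHOICES[:-1],
                                    WORKED_EXAMPLE_REWARDS[:-1], WX_PARAMS)
        c1, c2, c3 = WORKED_EXAMPLE_CHOICES[-1]
        s2, s3 = c1, 2 * c1 + c2
        assert qvals[-1, 0, :] == pytest.approx([q_prev[("s1", 0, 0)], q_prev[("s1", 0, 1)]])
        assert qvals[-1, 1, :] == pytest.approx([q_prev[("s2", s2, 0)], q_prev[("s2", s2, 1)]])
        assert qvals[-1, 2, :] == pytest.approx([q_prev[("s3", s3, 0)], q_prev[("s3", s3, 1)]])

    def test_one_trial_beta_zero(self, worked_example):
        p = sv.AgentParams(0.3, 0.3, 0.3, 0.5, 0, 0, 0)
        assert sv.sequence_log_likelihood(worked_example.head(1), p) == \
            pytest.approx(-3 * np.log(2))

    def test_generating_params_dominate_mismatched_betas(self, walk):
        gen = sv.AgentParams(0.4, 0.4, 0.4, 0.7, 8, 8, 8)
        frames = [sv.simulate_agent(gen, walk, seed=s) for s in (1, 2, 3)]
        sim = pd.concat(frames, ignore_index=True)
        sim["block"] = np.arange(len(sim)) // walk.trials_per_block + 1
        sim["trial"] = np.arange(len(sim)) % walk.trials_per_block + 1
        low = sv.AgentParams(0.4, 0.4, 0.4, 0.7, 0.1, 0.1, 0.1)
        assert sv.sequence_log_likelihood(sim, gen) > sv.sequence_log_likelihood(sim, low)

    def test_action_label_symmetry(self, worked_example):
        """Flipping both the action labels and the visited states leaves
        the likelihood unchanged."""
        flipped = worked_example.copy()
        for c in ("choice_s1", "choice_s2", "choice_s3"):
            flipped[c] = 1 - flipped[c]
        flipped["state_s2"] = flipped["choice_s1"]
        flipped["state_s3"] = 2 * flipped["choice_s1"] + flipped["choice_s2"]
        assert sv.sequence_log_likelihood(flipped, WX_PARAMS) == \
            pytest.approx(sv.sequence_log_likelihood(worked_example, WX_PARAMS), abs=1e-10)


class TestSimulation:
    def test_random_policy_choice_rates(self, walk):
        p = sv.AgentParams(0.3, 0.3, 0.3, 0.5, 0, 0, 0)
        frames = [sv.simulate_agent(p, walk, seed=s) for s in range(25)]
        sim = pd.concat(frames)
        for c in ("choice_s1", "choice_s2", "choice_s3"):
            assert abs(sim[c].mean() - 0.5) < 0.03

    def test_zero_learning_rate_constant_trace(self, walk):
        p = sv.AgentParams(0, 0, 0, 0.5, 3, 3, 3)
        sim = sv.simulate_agent(p, walk, seed=0)
        for k in (1, 2, 3):
            assert (sim[f"q_s{k}_0"] == Q_INIT).all()
            assert (sim[f"absdq_s{k}"] == 0).all()

    def test_learning_beats_chance_at_stage_three(self):
        from scipy.stats import binomtest
        cfg = sv.TaskConfig(n_blocks=10, trials_per_block=50, seed=3)
        walk = sv.make_reward_walk(cfg)
        p = sv.AgentParams(0.7, 0.7, 0.7, 1.0, 15, 15, 15)
        frames = [sv.simulate_agent(p, walk, seed=s) for s in (10, 11, 12, 13)]
        sim = pd.concat(frames, ignore_index=True)
        # correct at stage 3 = chose the chest with higher true probability
        t = np.tile(np.arange(walk.n_trials), 4)
        s3 = sim["state_s3"].to_numpy()
        probs = walk.probs[t]
        left = probs[np.arange(len(sim)), 2 * s3]
        right = probs[np.arange(len(sim)), 2 * s3 + 1]
        chose_right = sim["choice_s3"].to_numpy() == 1
        correct = np.where(chose_right, right >= left, left >= right)
        res = binomtest(int(correct.sum()), len(correct), 0.5, alternative="greater")
        assert res.pvalue < 0.001
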
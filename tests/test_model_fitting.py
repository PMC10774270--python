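import numpy as np
import pandas as pd
import pytest

import seqvalue as sv
from seqvalue.model_fitting import ModelSpec, SATURATED, GroupPosterior
from seqvalue.rl_model import PARAM_NAMES, params_to_transformed

from _oracles import oracle_offered_values


class TestModelSpec:
    @pytest.mark.parametrize("spec,n", [
        (ModelSpec(False, False, True), 7),
        (ModelSpec(True, False, True), 5),
        (ModelSpec(False, True, True), 5),
        (ModelSpec(True, True, True), 3),
        (ModelSpec(True, True, False), 2),
    ])
    def test_parameter_counts(self, spec, n):
        assert spec.n_params == n
        assert len(spec.reduced_names) == n

    def test_natural_mapping_saturated(self):
        from scipy.special import expit
        theta = np.array([0.1, -0.2, 0.3, 0.0, np.log(2), np.log(3), np.log(4)])
        nat = SATURATED.natural(theta)
        assert nat[:4] == pytest.approx(expit(theta[:4]))
        assert nat[4:] == pytest.approx([2, 3, 4])

    def test_fixed_lambda_maps_to_one(self):
        spec = ModelSpec(True, True, False)
        nat = spec.natural(np.array([0.0, 0.0]))
        assert nat[3] == 1.0
        assert np.allclose(nat[0:3], 0.5) and np.allclose(nat[4:], 1.0)


@pytest.fixture(scope="module")
def small_fit():
    """One 6-participant cohort and its (short-chain) hierarchical fit."""
    cfg = sv.CohortConfig(n_hc=6, n_adhd=1, env=sv.TaskConfig(2, 40), seed=31)
    pub, truth = sv.generate_cohort(cfg)
    hc = pub[pub["group"] == "HC"]
    post = sv.fit_hierarchical(hc, n_warmup=300, n_draws=400, n_chains=2, seed=5)
    return {"cohort": hc, "truth": truth, "post": post}


class TestFitHierarchical:
    def test_posterior_shapes_and_diagnostics(self, small_fit):
        post = small_fit["post"]
        assert post.theta_nat.shape == (2, 400, 6, 7)
        assert post.mu_draws.shape == (2, 400, 7)
        assert set(post.diagnostics["rhat"]) == {f"mu_{n}" for n in SATURATED.reduced_names}
        assert post.diagnostics["min_ess"] > 0

    def test_participant_means_respect_bounds(self, small_fit):
        m = small_fit["post"].participant_means()
        for a in ("alpha1", "alpha2", "alpha3", "lam"):
            assert m[a].between(0, 1).all()
        for b in ("beta1", "beta2", "beta3"):
            assert (m[b] > 0).all() and (m[b] <= 20).all()

    def test_posterior_predictive_choice_behaviour(self, small_fit):
        """Cohorts re-simulated at fitted parameters should behave like
        the fitted cohort (reward rate and stage-1 switch rate)."""
        post, truth = small_fit["post"], small_fit["truth"]
        cohort = small_fit["cohort"]
        walk = truth["walk"]
        sims = []
        for i, (_, row) in enumerate(post.participant_means().iterrows()):
            p = sv.AgentParams.from_array(row[list(PARAM_NAMES)].to_numpy(dtype=float))
            sims.append(sv.simulate_agent(p, walk, seed=100 + i))
        sim = pd.concat(sims)
        assert abs(sim["reward"].mean() - cohort["reward"].mean()) < 0.07
        emp_sw = (cohort["choice_s1"].to_numpy()[1:] != cohort["choice_s1"].to_numpy()[:-1]).mean()
        sim_sw = (sim["choice_s1"].to_numpy()[1:] != sim["choice_s1"].to_numpy()[:-1]).mean()
        assert abs(emp_sw - sim_sw) < 0.12

    def test_mixed_group_input_rejected(self, small_fit):
        both = pd.concat([small_fit["cohort"].head(40),
                          small_fit["cohort"].head(40).assign(group="ADHD")])
        with pytest.raises(ValueError, match="one group"):
            sv.fit_hierarchical(both, n_warmup=10, n_draws=10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sv.fit_hierarchical(pd.DataFrame(columns=["participant_id", "group"]))

    def test_single_participant_self_consistency(self):
        """With many trials the posterior concentrates around the
        generating parameters."""
        gen = sv.AgentParams(0.3, 0.3, 0.3, 0.5, 5, 5, 5)
        walk = sv.make_reward_walk(sv.TaskConfig(n_blocks=4, trials_per_block=200, seed=9))
        sim = sv.simulate_agent(gen, walk, seed=10)
        sim.insert(0, "participant_id", "S1")
        sim.insert(1, "group", "HC")
        post = sv.fit_hierarchical(sim, n_warmup=500, n_draws=600, n_chains=2, seed=3)
        ci = post.participant_ci(0.95)
        gen_arr = gen.as_array()
        inside = [(ci["lo"][0, j] <= gen_arr[j] <= ci["hi"][0, j]) for j in range(7)]
        assert sum(inside) >= 6, dict(zip(PARAM_NAMES, inside))

    def test_two_cohorts_order_alpha1(self):
        """Populations generated at alpha1 ~ 0.2 vs 0.6 separate in the
        group-level posterior with pd > 95%."""
        walk = sv.make_reward_walk(sv.TaskConfig(2, 75, seed=13))
        posts = []
        for mean_a1, seed in ((0.2, 0), (0.6, 1)):
            nat = np.array([mean_a1, 0.35, 0.35, 0.6, 5.0, 5.0, 5.0])
            dist = sv.GroupParamDist(params_to_transformed(nat),
                                     np.array([0.3] * 4 + [0.25] * 3))
            rng = np.random.default_rng(50 + seed)
            frames = []
            for i in range(10):
                p = sv.AgentParams.from_array(dist.draw(1, rng)[0])
                df = sv.simulate_agent(p, walk, seed=rng)
                df.insert(0, "participant_id", f"S{i}")
                df.insert(1, "group", "HC")
                frames.append(df)
            posts.append(sv.fit_hierarchical(pd.concat(frames, ignore_index=True),
                                             n_warmup=500, n_draws=600, seed=seed))
        j = SATURATED.reduced_names.index("alpha1")
        diff = posts[1].mu_draws[..., j].reshape(-1) - posts[0].mu_draws[..., j].reshape(-1)
        k = min(diff.size, posts[0].mu_draws[..., j].size)
        pd_ = 100 * max(np.mean(diff[:k] > 0), np.mean(diff[:k] < 0))
        assert np.median(diff) > 0
        assert pd_ > 95


class TestExtractQ:
    def _point_posterior(self, cohort, params_by_pid):
        pids = sorted(params_by_pid)
        nat = np.array([params_by_pid[p] for p in pids])
        theta = np.tile(nat, (2, 150, 1, 1))
        return GroupPosterior(
            spec=SATURATED, group="HC", participant_ids=pids,
            theta_nat=theta, theta_trans=params_to_transformed(theta),
            mu_draws=np.zeros((2, 150, 7)), sigma_draws=np.ones((2, 150, 7)),
            diagnostics={})

    def test_zero_learning_gives_zero_dq(self, tiny_cohort):
        df = tiny_cohort["trials"]
        sub = df[df["participant_id"] == df["participant_id"].iloc[0]]
        post = self._point_posterior(sub, {
            sub["participant_id"].iloc[0]: [0, 0, 0, 0.5, 2, 2, 2]})
        qt = sv.extract_q_trajectories(post, sub)
        # alpha passes through a clipped logit link, so "zero" is ~1e-9
        np.testing.assert_allclose(qt["abs_dq"], 0.0, atol=1e-7)
        np.testing.assert_allclose(qt["q_chosen"], 0.5, atol=1e-7)

    def test_point_posterior_equals_deterministic_replay(self, worked_example):
        params = [0.25, 0.35, 0.45, 0.6, 2, 3, 4]
        post = self._point_posterior(worked_example, {"WX01": params})
        a = sv.extract_q_trajectories(post, worked_example)
        b = sv.extract_q_trajectories(post, worked_example, draw_average=True)
        np.testing.assert_allclose(a["abs_dq"], b["abs_dq"], atol=1e-12)

    def test_draw_average_matches_brute_force(self, worked_example):
        """Averaged replay equals the mean of per-draw oracle replays."""
        from seqvalue.synthetic_data import (WORKED_EXAMPLE_CHOICES,
                                             WORKED_EXAMPLE_REWARDS)
        rng = np.random.default_rng(4)
        draws = np.column_stack([rng.uniform(0.1, 0.9, (100, 4)),
                                 rng.uniform(0.5, 6, (100, 3))])
        theta = np.tile(draws.reshape(1, 100, 1, 7), (2, 1, 1, 1))
        post = GroupPosterior(
            spec=SATURATED, group="HC", participant_ids=["WX01"],
            theta_nat=theta, theta_trans=params_to_transformed(theta),
            mu_draws=np.zeros((2, 100, 7)), sigma_draws=np.ones((2, 100, 7)),
            diagnostics={})
        qt = sv.extract_q_trajectories(post, worked_example, draw_average=True,
                                       max_draws=200)
        oracle = np.mean([
            oracle_offered_values(WORKED_EXAMPLE_CHOICES, WORKED_EXAMPLE_REWARDS,
                                  sv.AgentParams.from_array(p))
            for p in np.vstack([theta[0, :, 0], theta[1, :, 0]])], axis=0)
        got = qt.pivot_table(index="trial", columns="stage", values="abs_dq")
        want = np.abs(oracle[:, :, 1] - oracle[:, :, 0])
        np.testing.assert_allclose(got.to_numpy(), want, atol=1e-10)

    def test_missing_participant_key_error(self, small_fit, tiny_cohort):
        with pytest.raises(KeyError):
            sv.extract_q_trajectories(small_fit["post"], tiny_cohort["trials"])


class TestCompareAndRecovery:
    def test_single_spec_rejected(self, small_fit):
        with pytest.raises(ValueError, match="two specs"):
            sv.compare_models(small_fit["cohort"], [SATURATED])

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            sv.run_parameter_recovery(0)

    def test_interval_width_shrinks_with_more_trials(self):
        """Average beta1 interval width decreases from 60 to 240 trials."""
        widths = []
        for tpb, seed in ((30, 3), (120, 4)):
            walk = sv.make_reward_walk(sv.TaskConfig(2, tpb, seed=seed))
            rng = np.random.default_rng(7)
            frames = []
            for i in range(6):
                p = sv.AgentParams(0.35, 0.35, 0.35, 0.6, 5, 5, 5)
                df = sv.simulate_agent(p, walk, seed=rng)
                df.insert(0, "participant_id", f"S{i}")
                df.insert(1, "group", "HC")
                frames.append(df)
            post = sv.fit_hierarchical(pd.concat(frames, ignore_index=True),
                                       n_warmup=300, n_draws=400, seed=seed)
            ci = post.participant_ci(0.89)
            j = list(PARAM_NAMES).index("beta1")
            widths.append(float(np.mean(ci["hi"][:, j] - ci["lo"][:, j])))
        assert widths[1] < widths[0]
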
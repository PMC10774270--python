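# seqvalue

Sequential value learning on a three-stage tree task: simulation,
hierarchical reinforcement-learning modelling, and Bayesian analyses of
choice accuracy and reaction-time variability.

## The problem

In multi-stage decision tasks (pick a house → a door → a chest, then
find out whether the chest pays off), the value of the final outcome
must be mentally propagated back to the earlier, *initiatory* actions.
A model-free learner does this with discounted prediction errors: the
first-stage value is updated by α₁·PE₁ + α₁λ·PE₂ + α₁λ²·PE₃, where
PE₁ = V_c2 − V_c1, PE₂ = V_c3 − V_c2, PE₃ = R − V_c3, λ is an
eligibility trace, and each stage chooses via a softmax with its own
inverse temperature β. Group differences in how well people *act on*
those backpropagated values — for instance, attenuated first-stage
value sensitivity in ADHD relative to controls — then show up as
stage-specific group × value-difference interactions in choice accuracy
and in the slow tail (ex-Gaussian τ) of the RT distribution.

This package implements that entire analysis chain for simulated
cohorts:

- `task_env` — deterministic 2×2×2 tree with drifting (reflected
  Gaussian random walk) chest reward probabilities;
- `rl_model` — the saturated 7-parameter agent (α₁..α₃, λ, β₁..β₃):
  updates, likelihoods, generative simulation;
- `io_schema` — trial-table schema, validation, accuracy/difficulty
  coding against the true walk, and the standard data-treatment rules
  (first trials, RTs outside [200, 4000] ms, missing feedback,
  participant-level thresholds);
- `model_fitting` — hierarchical Bayesian estimation per group
  (adaptive Metropolis-within-Gibbs; arviz diagnostics), PSIS-LOO
  nested model comparison, trial-level internal-value (|ΔQ|)
  extraction, and parameter recovery;
- `exgauss` — ex-Gaussian density/MLE and a hierarchical
  distributional regression on log τ;
- `regressions` — the two hierarchical analyses
  (accuracy ~ predictor × group × stage, log τ ~ predictor × group ×
  stage) with median / CI89 / CI95 / probability-of-direction
  summaries;
- `synthetic_data` — a two-group cohort generator whose single planted
  group difference is a stage-1 decision-temperature deficit;
- `pipeline_cli` — the `seqvalue` command line and a resumable
  end-to-end pipeline with a run manifest.

## Worked example

```python
import pandas as pd
import seqvalue as sv

# simulate a cohort: 26 HC + 28 ADHD, beta1 deficit only
cfg = sv.CohortConfig(env=sv.TaskConfig(2, 50), seed=11)
trials, truth = sv.generate_cohort(cfg)
clean, report = sv.apply_exclusions(trials)

# per-group hierarchical fit and internal-value extraction
qtraj = pd.concat([
    sv.extract_q_trajectories(sv.fit_hierarchical(sub, seed=3), sub)
    for _, sub in clean.groupby("group")], ignore_index=True)
long = sv.build_regression_table(clean, qtraj=qtraj, predictor="abs_dq")

acc = sv.accuracy_regression(long, seed=4).summaries()
print(acc["stage1:group_x"])
print(acc["stage3:group_x"])
```

Output from this exact run:

```
PosteriorSummary(median=-1.2343993271494265, ci89=(-2.02989895229844, -0.5161799239684534), ci95=(-2.198538372152647, -0.3473601742423813), pd=99.77777777777777)
PosteriorSummary(median=0.49931046679781765, ci89=(-0.11660792896433192, 1.109976465990674), ci95=(-0.28510648612135037, 1.2560468453898923), pd=91.61111111111111)
```

Read: the ADHD group's stage-1 accuracy is less sensitive to the
internal value difference than the HC group's (negative group × |ΔQ|
interaction, pd ≈ 98%), while at stage 3 the 89% interval covers zero —
the groups are indistinguishable for the terminal action. The matching
RT analysis (`sv.rt_variability_regression(long)`) shows the mirror
pattern on log τ: a positive stage-1 contrast (the ADHD slow tail does
not shrink with |ΔQ|) and a stage-3 contrast covering zero.

## Command line

```bash
seqvalue synth --seed 7 --out cohort.csv
seqvalue exclude cohort.csv --out clean.csv
seqvalue fit clean.csv --group HC --fast --out params_hc.csv
seqvalue run --seed 7 --fast --out runs/demo && seqvalue report runs/demo
```

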
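# Methods

## The task and its simulator

The environment is a three-stage deterministic binary tree: a first
choice between two houses, a second between two doors (conditional on
the house), and a third between two chests (conditional on the door),
ending at one of 8 leaves. Each leaf pays a 0/1 reward with a
probability that follows a reflected Gaussian random walk, so value has
to be tracked continuously. Walk defaults: step sd 0.025 per trial,
bounds [0.25, 0.75], 4 blocks of 50 trials. These drift dynamics and
session sizes are package defaults chosen from the multi-step
bandit-task literature's usual ranges; all are configurable
(`TaskConfig`). Reflection rather than truncation at the bounds avoids
probability mass piling up at the edges. The walk is one continuous
process across blocks; block boundaries matter only for data treatment
and the optional per-block value reset.

## The learning model

Each agent carries 14 state-action values (2 houses, 4 doors, 8
chests), initialized at 0.5, the midpoint of the reward range (this
also makes the containment property below hold). After each trial three
prediction errors are formed from the *pre-update* values,

    PE1 = V_c2 − V_c1,  PE2 = V_c3 − V_c2,  PE3 = R − V_c3,

and applied with stage learning rates α₁..α₃ and eligibility trace λ:

    V_c1 += α₁·PE1 + α₁λ·PE2 + α₁λ²·PE3
    V_c2 += α₂·PE2 + α₂λ·PE3
    V_c3 += α₃·PE3

Unchosen actions are never updated. λ=1 telescopes the first update to
α₁(R − V_c1) (whole-sequence learning); λ=0 gives three independent
one-step TD learners. Choices are softmax with stage temperatures
β₁..β₃. Because the update weights form convex combinations for
α, λ ∈ [0,1] and R ∈ {0,1}, values initialized in [0,1] can never leave
it; this is property-tested.

Two modelling choices the equations leave open are exposed as
configuration: values persist across blocks by default
(`reset_per_block=False`), and the initial value is `q0=0.5`.

## Hierarchical Bayesian estimation

Participant parameters are Gaussian individual effects on an
unconstrained scale — logit for α and λ, log for β (β capped at 20 to
rule out numerically degenerate deterministic policies). Population
priors per parameter: location ~ Normal(0, 1.5), scale ~ half-Normal(1),
standard weakly-informative defaults for hierarchical RL. Groups are
fitted separately with no shared hyperpriors.

No probabilistic-programming backend is used: the posterior is sampled
with an adaptive Metropolis-within-Gibbs scheme written for this
package (`_samplers.py`) — component-wise random-walk updates with
Robbins–Monro step adaptation for participant vectors, a conjugate
Gibbs draw for each population location, a log-scale random walk for
each population scale, and (in the regression models) an additional
joint proposal whose covariance is learned during warmup. Two chains
are run by default; R-hat and bulk ESS are computed with arviz and
attached to every fit, with a flag raised above R-hat 1.01. Random-walk
kernels have no divergences; the diagnostics field keeps the slot for
report compatibility.

Point estimates per participant are posterior means taken on the
estimation scale and mapped through the link (e.g. exp of the mean of
log-β draws). This is the estimator consistent with the sampled
parameterization; averaging natural-scale draws instead would inflate β
through the convexity of exp.

Model comparison fits each nested specification to the pooled cohort
and ranks by PSIS-LOO (arviz) on trial-wise choice log-likelihood; the
comparison criterion is a package default, chosen because it estimates
out-of-sample predictive density with a standard error. In a reduced
spec, `free_lambda=False` fixes λ=1 — the whole-sequence Monte-Carlo
learner — as the natural nested alternative to estimating the trace.

Internal action values (`extract_q_trajectories`) replay each
participant's observed sequence at their posterior-mean parameters by
default; the draw-averaged replay (the literal expected-value reading)
is available behind `draw_average=True`, and the two coincide as
learning rates shrink. |ΔQ| is the absolute difference of the two
offered values per trial and stage.

## Behaviour coding and data treatment

A choice is correct when the chosen option's value is at least the
alternative's, where an option's value at stages 1–2 is the maximum
true chest probability reachable through it (best completion;
`option_value="mean"` is available). Difficulty is the absolute
difference of the two option values. Exact ties are coded correct:
with continuously drifting probabilities they have measure zero, and
dropping them would discard trials for no information.

Data treatment removes, in order: the first trial of each block, trials
with any stage RT outside [200, 4000] ms (no-responses — missing RT and
choice — count here too), and trials without feedback. Participants are
dropped at >25% excluded trials, >5% no-response trials, or >5%
missing-feedback trials, all on pre-removal denominators (the whole
point of the fractions is "of all trials"). Exclusion is idempotent.

## Ex-Gaussian RT model

The RT density is the Normal(μ, σ) ⊕ Exponential(τ) convolution with
mean μ+τ and variance σ²+τ². The log-density uses the log-Φ form with
an asymptotic branch for σ/τ > 10⁴, where the closed form cancels
catastrophically; the branch limits smoothly to the Normal log-density.
MLE fitting uses moment-based starts (skewness-derived τ) and
Nelder–Mead on (μ, log σ, log τ).

RT-variability regression is distributional: per-participant μᵢ, σᵢ,
a participant random intercept on log τ, and fixed effects on log τ
carrying the predictor × group × stage structure. The log link is
forced by τ's positivity. Random slopes are not fitted by default
(random-intercepts-only), a deliberate simplification at these cohort
sizes. Of the two readings of "τ per condition" — binned two-stage
fitting vs a single trial-level distributional regression — the
package implements the distributional regression as the primary path
because it uses every trial; the binned route can be assembled from
`fit_exgauss` on condition subsets.

## The two regressions

Both analyses share one design: per-stage intercepts, per-stage
predictor slopes, per-stage group offsets (ADHD indicator), and
per-stage group × predictor interactions (12 fixed effects), plus
participant random intercepts. The predictor is either the
theory-independent choice difficulty or the model-derived |ΔQ|, both on
the [0,1] scale and entered raw. Accuracy uses a hierarchical logistic
model; when the predictor is |ΔQ|, accuracy is re-coded as choosing the
higher internal value. Coefficient priors are Normal(0, 2.5);
participant-intercept scale half-Normal(1).

Summaries follow the Bayesian reporting convention: posterior median,
equal-tailed 89% and 95% credible intervals (HDI not implemented;
equal-tailed is the package's convention), and probability of
direction pd = max(P(>0), P(<0))·100. The marginal accuracy effect of
a predictor change δ is computed on the probability scale from the
cohort-mean predictor as reference, averaged over posterior draws and
participant intercepts.

An empirical note: with a model-free learner on this walk, the
theory-independent difficulty regressor correlates only weakly with the
agent's internal |ΔQ| at stage 1 (both houses' best completions drift
close together), so group contrasts planted in the decision
temperatures are reliably visible in the |ΔQ| analyses but not in the
difficulty analyses; the difficulty route also picks up a mediated
visitation effect at stage 3 (noisier first-stage choices spread
learning over more chests). The end-to-end checks therefore exercise
the model-derived path, mirroring the computational analysis.

## The synthetic cohort generator

The generator is the package's stand-in for a two-group study cohort:
26 HC and 28 ADHD participants, 200 trials each by default. Participant
parameters are drawn from a common population (α ~ logit-normal around
0.35, λ around 0.6, β ~ log-normal around 5) with a single planted
group difference: the ADHD β₁ location is shifted by −0.8 on the log
scale (≈ a factor 0.45), the attenuated-initiatory-sensitivity locus;
an optional α₁ shift supports robustness experiments. Stage RTs are
ex-Gaussian (μ=450, σ=80, base τ=150 ms) with log τ coupled to the
agent's trial-level |ΔQ|: slope −0.8 everywhere except the ADHD stage-1
slope, which is 0 — so lower |ΔQ| lengthens the slow RT tail for
everyone except that one cell, giving the τ regression a recoverable
stage-1-only contrast. Effect sizes are chosen for testability, not
estimated from data. A small missing-feedback rate (0.5%) exercises the
exclusion rules.

What the generator does *not* emulate: post-error slowing, RT
autocorrelation, lapses/attention drift, practice effects, μ/σ changes
with difficulty, and any model-based planning component. Passing tests
therefore show that the pipeline recovers structure *of the kind it
assumes*, not that real cohorts satisfy these assumptions.

## Problem sizes and numerics

The test-suite and acceptance runs use reduced problem sizes chosen as
the package's fast-mode defaults: headline cohorts of 26+28
participants × 100 trials, recovery at 28 × 200 (the study-scale
condition), model selection on 12 participants × 150 trials, null
calibration on 20 replicates of 8+8 × 60. MCMC settings scale
accordingly (warmup 250–1600, draws 350–2000, 2 chains). Degenerate
inputs fail fast: empty cohorts, single-group contrasts, constant
predictors, constant RT samples, and sub-minimum sample sizes all raise
informative errors rather than producing numbers.

Known limitations: random-walk MCMC needs these warmup lengths to mix
(R-hat up to ~1.2 on the slowest regression coefficients at fast-mode
settings); recovery point estimates inherit hierarchical shrinkage, so
cohort-level mean bias for β reflects both estimation noise (SE ≈ 0.17
at n=28) and the variance-compression of shrunken log-scale estimates
mapped through exp; and the likelihood treats the three stage choices
as conditionally independent given values, so RTs never inform the
choice model.
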
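"""Hierarchical Bayesian regressions for choice accuracy and RT variability.

Both analyses share one design: an outcome is predicted from a
trial-level difficulty regressor x (either the theory-independent choice
difficulty, i.e. the absolute difference of the true expected values of
the two offers, or the model-derived |dQ|), crossed with group
(HC vs ADHD) and stage (1, 2, 3). Stage enters categorically with
stage-specific predictor slopes, group offsets, and group-by-predictor
interactions; participants contribute random intercepts. The accuracy
model is logistic; the RT-variability model is the distributional
ex-Gaussian regression with the linear predictor on log(tau).

Posterior summaries follow the reporting convention of Bayesian
cognitive-modelling papers: median, equal-tailed 89% and 95% credible
intervals, and the probability of direction (pd), the posterior
probability that a coefficient shares the sign of its median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._samplers import (BlockStep, ScalarStep, half_normal_logpdf, mh_accept,
                        normal_logpdf, diagnostics)
from . import exgauss

STAGES = (1, 2, 3)
COEF_PRIOR_SD = 2.5


@dataclass(frozen=True)
class PosteriorSummary:
    median: float
    ci89: tuple[float, float]
    ci95: tuple[float, float]
    pd: float  # probability of direction, percent in [50, 100]

    def as_dict(self) -> dict:
        return {"median": self.median, "ci89_lo": self.ci89[0], "ci89_hi": self.ci89[1],
                "ci95_lo": self.ci95[0], "ci95_hi": self.ci95[1], "pd": self.pd}


def summarize_posterior(draws: np.ndarray) -> PosteriorSummary:
    """Median, 89%/95% equal-tailed intervals and pd of a draw vector."""
    x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size < 100:
        raise ValueError(f"need at least 100 draws, got {x.size}")
    med = float(np.median(x))
    ci89 = tuple(float(v) for v in np.quantile(x, [0.055, 0.945]))
    ci95 = tuple(float(v) for v in np.quantile(x, [0.025, 0.975]))
    p_pos = float(np.mean(x > 0))
    pd_ = 100.0 * max(p_pos, 1.0 - p_pos)
    return PosteriorSummary(med, ci89, ci95, pd_)


def summary_table(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame({k: v.as_dict() for k, v in summaries.items()}).T


# ---------------------------------------------------------------------------
# Long-format table and design matrix
# ---------------------------------------------------------------------------

def build_regression_table(trials: pd.DataFrame, codes: pd.DataFrame | None = None,
                           qtraj: pd.DataFrame | None = None,
                           predictor: str = "difficulty") -> pd.DataFrame:
    """One row per trial-stage with outcome, predictor and stage RT.

    predictor="difficulty" uses the behaviour codes (true-value coding);
    predictor="abs_dq" uses extracted internal-value trajectories, with
    accuracy re-coded as choosing the higher internal value.
    """
    if predictor == "difficulty":
        if codes is None:
            if "difficulty_s1" not in trials.columns:
                raise ValueError("difficulty predictor needs the behaviour codes")
            t = trials
        else:
            overlap = [c for c in codes.columns if c in trials.columns]
            t = pd.concat([trials.drop(columns=overlap).reset_index(drop=True),
                           codes.reset_index(drop=True)], axis=1)
        rows = []
        for k in STAGES:
            rows.append(pd.DataFrame({
                "participant_id": t["participant_id"], "group": t["group"],
                "stage": k, "correct": t[f"correct_s{k}"].astype(int),
                "x": t[f"difficulty_s{k}"].astype(float),
                "rt": t[f"rt_s{k}"].astype(float),
            }))
        return pd.concat(rows, ignore_index=True)
    if predictor == "abs_dq":
        if qtraj is None:
            raise ValueError("abs_dq predictor needs extracted Q trajectories")
        merged = qtraj.merge(
            trials[["participant_id", "group", "block", "trial",
                    "rt_s1", "rt_s2", "rt_s3"]],
            on=["participant_id", "block", "trial"], how="left")
        rt = np.choose(merged["stage"].to_numpy() - 1,
                       [merged["rt_s1"], merged["rt_s2"], merged["rt_s3"]])
        return pd.DataFrame({
            "participant_id": merged["participant_id"], "group": merged["group"],
            "stage": merged["stage"].astype(int),
            "correct": (merged["q_chosen"] >= merged["q_unchosen"]).astype(int),
            "x": merged["abs_dq"].astype(float),
            "rt": rt,
        })
    raise ValueError(f"unknown predictor {predictor!r}")


def _design(long: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-stage intercept, slope, group offset and group-by-slope columns."""
    groups = sorted(long["group"].unique())
    if len(groups) < 2:
        raise ValueError("both groups must be present (group contrast undefined)")
    g = (long["group"] == "ADHD").to_numpy(dtype=float)
    x = long["x"].to_numpy(dtype=float)
    cols, names = [], []
    for k in STAGES:
        s = (long["stage"] == k).to_numpy(dtype=float)
        cols += [s, s * x, s * g, s * g * x]
        names += [f"stage{k}:intercept", f"stage{k}:x",
                  f"stage{k}:group", f"stage{k}:group_x"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design (e.g. constant predictor); "
                         "coefficients unidentified")
    return X, names


# ---------------------------------------------------------------------------
# Hierarchical logistic accuracy model
# ---------------------------------------------------------------------------

@dataclass
class AccuracyFit:
    coef_draws: np.ndarray      # (chain, draw, p)
    coef_names: list[str]
    participant_ids: list
    u_mean: np.ndarray          # posterior-mean participant intercepts
    x_ref: float                # cohort-mean predictor (marginal-effect reference)
    diagnostics: dict

    def coef(self, name: str) -> np.ndarray:
        return self.coef_draws[..., self.coef_names.index(name)].reshape(-1)

    def summaries(self) -> dict[str, PosteriorSummary]:
        return {n: summarize_posterior(self.coef(n)) for n in self.coef_names}


def _fit_hier_logistic(y: np.ndarray, X: np.ndarray, participant: np.ndarray,
                       coef_names: list[str], n_warmup: int, n_draws: int,
                       n_chains: int, seed: int) -> tuple[np.ndarray, np.ndarray, list, dict]:
    pids, pidx = np.unique(participant, return_inverse=True)
    n_p, p = pids.size, X.shape[1]
    order = np.argsort(pidx, kind="stable")
    y_o, X_o, pidx_o = y[order], X[order], pidx[order]
    bounds = np.searchsorted(pidx_o, np.arange(n_p + 1))
    sign = 1.0 - 2.0 * y_o  # ll = -logaddexp(0, sign*eta)

    def rows_ll(eta, sl=slice(None)):
        return -np.logaddexp(0.0, sign[sl] * eta)

    # non-hierarchical GLM solution as a start point and preconditioner
    b_init = np.zeros(p)
    try:
        import statsmodels.api as sm
        glm = sm.GLM(y_o, X_o, family=sm.families.Binomial())
        b_init = np.asarray(glm.fit(maxiter=50).params, dtype=float)
        b_init = np.clip(b_init, -8.0, 8.0)
    except Exception:  # separation etc.: fall back to zeros
        pass

    def run_chain(chain_seed):
        rng = np.random.default_rng(chain_seed)
        b = b_init + rng.normal(0, 0.1, p)
        u = rng.normal(0, 0.1, n_p)
        log_su = np.log(0.3)
        eta_fix = X_o @ b
        cur_ll = np.array([float(np.sum(rows_ll(eta_fix[bounds[i]:bounds[i + 1]] + u[i],
                                                slice(bounds[i], bounds[i + 1]))))
                           for i in range(n_p)])
        step_b = BlockStep(p, init_scale=0.05)
        steps_bj = [ScalarStep(0.1) for _ in range(p)]
        steps_u = [ScalarStep(0.2) for _ in range(n_p)]
        step_su = ScalarStep(0.2)
        out_b = np.empty((n_draws, p))
        u_acc = np.zeros(n_p)
        kept = 0

        def try_fixed(prop_b, scalar_j=None):
            nonlocal b, eta_fix, cur_ll
            prop_eta = X_o @ prop_b
            new_rows = rows_ll(prop_eta + u[pidx_o])
            new_ll = np.add.reduceat(new_rows, bounds[:-1])
            lr = (float(np.sum(new_ll) - np.sum(cur_ll))
                  + float(np.sum(normal_logpdf(prop_b, 0.0, COEF_PRIOR_SD)
                                 - normal_logpdf(b, 0.0, COEF_PRIOR_SD))))
            acc = mh_accept(lr, rng)
            if acc:
                b, eta_fix, cur_ll = prop_b, prop_eta, new_ll
            return acc

        for it in range(n_warmup + n_draws):
            warm = it < n_warmup
            su = np.exp(log_su)
            # scalar sweeps keep moving while the joint proposal learns
            # the posterior correlation structure
            for j in range(p):
                prop_b = b.copy()
                prop_b[j] += steps_bj[j].s * rng.standard_normal()
                acc = try_fixed(prop_b)
                if warm:
                    steps_bj[j].adapt(acc)
            acc = try_fixed(step_b.propose(b, rng))
            if warm:
                step_b.scale.adapt(acc)
                step_b.update_cov(b)
            for i in range(n_p):
                sl = slice(bounds[i], bounds[i + 1])
                prop = u[i] + steps_u[i].s * rng.standard_normal()
                new = float(np.sum(rows_ll(eta_fix[sl] + prop, sl)))
                lr = (new - cur_ll[i]
                      + float(normal_logpdf(prop, 0.0, su))
                      - float(normal_logpdf(u[i], 0.0, su)))
                acc = mh_accept(lr, rng)
                if acc:
                    u[i], cur_ll[i] = prop, new
                if warm:
                    steps_u[i].adapt(acc)
            prop_ls = log_su + step_su.s * rng.standard_normal()
            lr = (float(np.sum(normal_logpdf(u, 0.0, np.exp(prop_ls))
                               - normal_logpdf(u, 0.0, np.exp(log_su))))
                  + half_normal_logpdf(np.exp(prop_ls), 1.0) + prop_ls
                  - half_normal_logpdf(np.exp(log_su), 1.0) - log_su)
            acc = mh_accept(lr, rng)
            if acc:
                log_su = prop_ls
            if warm:
                step_su.adapt(acc)
            if not warm:
                out_b[kept] = b
                u_acc += u
                kept += 1
        return out_b, u_acc / max(kept, 1)

    ss = np.random.SeedSequence(seed)
    bs, us = [], []
    for cs in ss.spawn(n_chains):
        ob, ou = run_chain(cs.generate_state(1)[0] % (2 ** 31))
        bs.append(ob)
        us.append(ou)
    coef_draws = np.stack(bs)
    diag = diagnostics(coef_draws, coef_names)
    return coef_draws, np.mean(us, axis=0), list(pids), diag


def accuracy_regression(long: pd.DataFrame, n_warmup: int = 600,
                        n_draws: int = 900, n_chains: int = 2,
                        seed: int = 0) -> AccuracyFit:
    """Hierarchical logistic model of correctness.

    ``long`` comes from :func:`build_regression_table`. The coefficients
    of interest are ``stage{k}:group_x``, the per-stage group-by-
    predictor contrasts (ADHD minus HC difference in predictor slope).
    """
    X, names = _design(long)
    y = long["correct"].to_numpy(dtype=float)
    coef_draws, u_mean, pids, diag = _fit_hier_logistic(
        y, X, long["participant_id"].to_numpy(), names,
        n_warmup, n_draws, n_chains, seed)
    return AccuracyFit(coef_draws, names, pids, u_mean,
                       float(long["x"].mean()), diag)


def rt_variability_regression(long: pd.DataFrame, n_warmup: int = 600,
                              n_draws: int = 800, n_chains: int = 2,
                              seed: int = 0) -> exgauss.TauRegressionResult:
    """Distributional ex-Gaussian model of stage RTs with log(tau) design.

    Delegates the observation model to :mod:`seqvalue.exgauss`; the
    linear predictor on log(tau) uses the same stage/group/predictor
    design as the accuracy model.
    """
    ok = long["rt"].notna()
    long = long.loc[ok]
    counts = long.groupby("participant_id").size()
    if (counts < 3).any():
        bad = list(counts[counts < 3].index)
        raise ValueError(f"too few RT observations per cell to fit the "
                         f"distributional model; offending participants: {bad}")
    X, names = _design(long)
    return exgauss.fit_tau_regression(
        long["rt"].to_numpy(dtype=float), X,
        long["participant_id"].to_numpy(), names,
        n_warmup=n_warmup, n_draws=n_draws, n_chains=n_chains, seed=seed)


def tau_summaries(res: exgauss.TauRegressionResult) -> dict[str, PosteriorSummary]:
    return {n: summarize_posterior(res.coef(n)) for n in res.coef_names}


def marginal_accuracy_effect(fit: AccuracyFit, delta: float = 0.5,
                             group: str = "HC", stage: int = 1,
                             reference: float | None = None) -> float:
    """Predicted accuracy change (probability scale) for a predictor
    change of ``delta`` from the reference point (cohort-mean predictor
    by default), averaged over posterior draws and participant
    intercepts."""
    import warnings

    x0 = fit.x_ref if reference is None else float(reference)
    if not (0.0 <= x0 + delta <= 1.0):
        warnings.warn(f"reference + delta = {x0 + delta:.3f} leaves the [0, 1] "
                      "predictor range; extrapolating", stacklevel=2)
    g = 1.0 if group == "ADHD" else 0.0

    def eta(x):
        b = {n: fit.coef_draws[..., i] for i, n in enumerate(fit.coef_names)}
        lin = (b[f"stage{stage}:intercept"] + b[f"stage{stage}:x"] * x
               + b[f"stage{stage}:group"] * g + b[f"stage{stage}:group_x"] * g * x)
        return lin[..., None] + fit.u_mean  # broadcast over participants

    from scipy.special import expit
    return float(np.mean(expit(eta(x0 + delta)) - expit(eta(x0))))
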
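"""Synthetic two-group cohorts with the statistical structure the
analysis pipeline assumes.

A cohort consists of HC and ADHD participants whose choices come from
the hierarchical RL agent on a shared drifting reward walk. Group
parameter distributions are identical except for a stage-1 decision
temperature deficit in the ADHD group (a negative shift on log(beta1)),
the locus of the effect under study: initiatory actions are chosen less
value-consistently while terminal actions are untouched. Per-stage
reaction times are ex-Gaussian with log(tau) linearly coupled to the
agent's trial-level |dQ| with group- and stage-specific slopes, so the
RT-variability regression has a recoverable ground truth; by default
only the HC group's stage-1 tau shrinks with |dQ|, mirroring the
attenuated stage-1 coupling in ADHD, while stages 2-3 couple equally in
both groups.

Effect sizes are chosen for testability of the pipeline, not estimated
from any dataset; the generator is synthetic by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_schema import REQUIRED_COLUMNS, save_trials
from .rl_model import AgentParams, GroupParamDist, PARAM_NAMES, simulate_agent
from .task_env import TaskConfig, RewardWalk, make_reward_walk


@dataclass
class RTModel:
    """Per-stage ex-Gaussian RT generator with |dQ|-coupled tau.

    log tau_it = log_tau0 + u_i + slope[group][stage] * absdq_it, with a
    participant intercept u_i ~ N(0, u_sd). mu and sigma are constant
    within participant (per-stage bases, identical by default).
    """

    mu: tuple[float, float, float] = (450.0, 450.0, 450.0)
    sigma: tuple[float, float, float] = (80.0, 80.0, 80.0)
    log_tau0: float = float(np.log(150.0))
    u_sd: float = 0.15
    slopes: dict = field(default_factory=lambda: {
        "HC": (-0.8, -0.8, -0.8),
        "ADHD": (0.0, -0.8, -0.8),
    })


@dataclass
class CohortConfig:
    n_hc: int = 26
    n_adhd: int = 28
    env: TaskConfig = field(default_factory=TaskConfig)
    hc_dist: GroupParamDist = field(default_factory=GroupParamDist.default)
    adhd_beta1_shift: float = -0.8   # log-scale stage-1 temperature deficit
    adhd_alpha1_shift: float = 0.0   # optional robustness mode (logit scale)
    rt: RTModel = field(default_factory=RTModel)
    feedback_missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_adhd < 1:
            raise ValueError("both groups need at least one participant")
        if self.adhd_beta1_shift > 0:
            raise ValueError("adhd_beta1_shift is a deficit, must be <= 0")

    def adhd_dist(self) -> GroupParamDist:
        return self.hc_dist.shifted(beta1=self.adhd_beta1_shift,
                                    alpha1=self.adhd_alpha1_shift)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the full cohort.

    Returns the public trial table (io_schema columns) and a
    ground-truth sidecar: the config, the shared reward walk, the
    per-participant generating parameters, and the latent trial table
    with Q traces, |dQ| and the generating tau per stage.
    """
    ss = np.random.SeedSequence(config.seed)
    s_env, s_draw = ss.spawn(2)
    walk = make_reward_walk(TaskConfig(
        config.env.n_blocks, config.env.trials_per_block, config.env.walk_sd,
        config.env.walk_bounds, config.env.init_probs,
        int(s_env.generate_state(1)[0] % (2 ** 31))))
    rng = np.random.default_rng(s_draw.generate_state(2))

    roster = ([("HC", config.hc_dist)] * config.n_hc
              + [("ADHD", config.adhd_dist())] * config.n_adhd)
    public_rows, latent_rows, param_rows = [], [], []
    counters = {"HC": 0, "ADHD": 0}
    for group, dist in roster:
        counters[group] += 1
        pid = f"{group}{counters[group]:02d}"
        nat = dist.draw(1, rng)[0]
        params = AgentParams.from_array(nat)
        sim = simulate_agent(params, walk, seed=rng)
        u_i = rng.normal(0.0, config.rt.u_sd)
        slopes = config.rt.slopes[group]
        for k in (1, 2, 3):
            tau = np.exp(config.rt.log_tau0 + u_i
                         + slopes[k - 1] * sim[f"absdq_s{k}"].to_numpy())
            rt = (rng.normal(config.rt.mu[k - 1], config.rt.sigma[k - 1], len(sim))
                  + rng.exponential(tau))
            sim[f"rt_s{k}"] = np.clip(rt, 1.0, None)
            sim[f"tau_s{k}"] = tau
        sim["feedback_shown"] = rng.random(len(sim)) >= config.feedback_missing_rate
        sim.insert(0, "participant_id", pid)
        sim.insert(1, "group", group)
        public_rows.append(sim[REQUIRED_COLUMNS].copy())
        latent_rows.append(sim)
        param_rows.append({"participant_id": pid, "group": group, "u_logtau": u_i,
                           **{n: nat[j] for j, n in enumerate(PARAM_NAMES)}})
    public = pd.concat(public_rows, ignore_index=True)
    truth = {
        "config": config,
        "walk": walk,
        "params": pd.DataFrame(param_rows),
        "latent": pd.concat(latent_rows, ignore_index=True),
    }
    return public, truth


def save_cohort(public: pd.DataFrame, truth: dict, csv_path, json_path) -> None:
    """Write the public CSV plus a JSON sidecar sufficient to regenerate it."""
    save_trials(public, csv_path)
    cfg = truth["config"]
    sidecar = {
        "config": _config_dict(cfg),
        "params": truth["params"].to_dict(orient="list"),
        "walk": truth["walk"].probs.tolist(),
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh)


def _config_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    env = d["env"]
    if env.get("init_probs") is not None:
        env["init_probs"] = list(np.asarray(env["init_probs"], dtype=float))
    d["hc_dist"] = {"mean": list(cfg.hc_dist.mean), "sd": list(cfg.hc_dist.sd)}
    return d


def config_from_dict(d: dict) -> CohortConfig:
    env = d.get("env", {})
    init = env.get("init_probs")
    task = TaskConfig(env.get("n_blocks", 4), env.get("trials_per_block", 50),
                      env.get("walk_sd", 0.025),
                      tuple(env.get("walk_bounds", (0.25, 0.75))),
                      None if init is None else np.asarray(init, dtype=float),
                      env.get("seed", 0))
    dist = GroupParamDist.default()
    if "hc_dist" in d:
        dist = GroupParamDist(np.asarray(d["hc_dist"]["mean"], dtype=float),
                              np.asarray(d["hc_dist"]["sd"], dtype=float))
    rt_d = d.get("rt", {})
    rt = RTModel(tuple(rt_d.get("mu", (450.0,) * 3)),
                 tuple(rt_d.get("sigma", (80.0,) * 3)),
                 rt_d.get("log_tau0", float(np.log(150.0))),
                 rt_d.get("u_sd", 0.15),
                 {k: tuple(v) for k, v in rt_d.get(
                     "slopes", {"HC": (-0.8,) * 3, "ADHD": (0.0, -0.8, -0.8)}).items()})
    return CohortConfig(d.get("n_hc", 26), d.get("n_adhd", 28), task, dist,
                        d.get("adhd_beta1_shift", -0.8),
                        d.get("adhd_alpha1_shift", 0.0), rt,
                        d.get("feedback_missing_rate", 0.005), d.get("seed", 0))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

# fixed 10-trial sequence whose Q trace is verifiable by hand / by a
# straight-line oracle: choices (c1, c2, c3) and terminal rewards
WORKED_EXAMPLE_CHOICES = [
    (0, 0, 0), (1, 1, 1), (0, 1, 0), (1, 0, 1), (0, 0, 1),
    (1, 1, 0), (0, 1, 1), (1, 0, 0), (0, 0, 0), (1, 1, 1),
]
WORKED_EXAMPLE_REWARDS = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]


def make_fixture(name: str) -> dict:
    """Packaged datasets for tests and examples.

    * ``tiny``: 2 participants x 12 trials, for schema/unit tests.
    * ``worked_example``: a fixed 10-trial single-participant sequence
      with a hand-verifiable value trace.
    * ``recovery``: the default 26+28 x 200-trial cohort.
    """
    if name == "tiny":
        cfg = CohortConfig(n_hc=1, n_adhd=1, env=TaskConfig(1, 12), seed=7)
        public, truth = generate_cohort(cfg)
        return {"trials": public, "truth": truth}
    if name == "worked_example":
        ch = np.array(WORKED_EXAMPLE_CHOICES, dtype=int)
        df = pd.DataFrame({
            "participant_id": "WX01", "group": "HC",
            "block": 1, "trial": np.arange(1, 11),
            "choice_s1": ch[:, 0], "choice_s2": ch[:, 1], "choice_s3": ch[:, 2],
            "state_s2": ch[:, 0], "state_s3": 2 * ch[:, 0] + ch[:, 1],
            "rt_s1": 500.0, "rt_s2": 500.0, "rt_s3": 500.0,
            "reward": WORKED_EXAMPLE_REWARDS, "feedback_shown": True,
        })
        return {"trials": df}
    if name == "recovery":
        cfg = CohortConfig(seed=2024)
        public, truth = generate_cohort(cfg)
        return {"trials": public, "truth": truth}
    raise ValueError(f"unknown fixture {name!r}")
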
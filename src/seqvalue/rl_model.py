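"""Model-free hierarchical reinforcement-learning agent for the tree task.

The agent carries one latent value per state-action pair (2 house values,
4 door values, 8 chest values; 14 in all). After each trial a prediction
error is formed at every stage,

    PE1 = V_choice2 - V_choice1
    PE2 = V_choice3 - V_choice2
    PE3 = R - V_choice3,

and backpropagated with an eligibility-trace discount lambda:

    V_choice1 += a1*PE1 + a1*lam*PE2 + a1*lam^2*PE3
    V_choice2 += a2*PE2 + a2*lam*PE3
    V_choice3 += a3*PE3,

all right-hand sides evaluated on the pre-update table. Choices at each
stage follow an independent softmax with stage-specific inverse
temperature beta. With lam=1 the agent updates whole sequences toward
the terminal outcome; with lam=0 each stage learns only from its local
one-step error. Unchosen actions are never updated.

The likelihood kernels are compiled with numba when available; a pure
NumPy fallback keeps the module importable without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_env import RewardWalk, transition

N_Q = 14  # 2 + 4 + 8 state-action values
Q_INIT = 0.5

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class AgentParams:
    """The saturated 7-parameter agent.

    alpha1..alpha3 are stage learning rates in [0, 1]; lam the
    eligibility trace in [0, 1]; beta1..beta3 stage decision
    temperatures >= 0 (higher = more value-consistent choice).
    """

    alpha1: float
    alpha2: float
    alpha3: float
    lam: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "lam"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.lam,
                         self.beta1, self.beta2, self.beta3], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "AgentParams":
        return cls(*(float(x) for x in a))


PARAM_NAMES = ("alpha1", "alpha2", "alpha3", "lam", "beta1", "beta2", "beta3")


class QTable:
    """Flat container of the 14 state-action values.

    Layout: indices 0-1 stage-1 actions; 2-5 stage-2 (2*state+action);
    6-13 stage-3 (2*state+action, i.e. the chest index + 6).
    """

    def __init__(self, values: np.ndarray | float = Q_INIT):
        if np.isscalar(values):
            self.q = np.full(N_Q, float(values))
        else:
            v = np.asarray(values, dtype=float)
            if v.shape != (N_Q,):
                raise ValueError(f"QTable needs {N_Q} values, got shape {v.shape}")
            self.q = v.copy()

    def copy(self) -> "QTable":
        return QTable(self.q)

    @staticmethod
    def index(stage: int, state: int, action: int) -> int:
        if stage == 1:
            return action
        if stage == 2:
            return 2 + 2 * state + action
        if stage == 3:
            return 6 + 2 * state + action
        raise ValueError(f"invalid stage {stage}")

    def value(self, stage: int, state: int, action: int) -> float:
        return float(self.q[self.index(stage, state, action)])

    def chosen_values(self, c1: int, c2: int, c3: int) -> tuple[float, float, float]:
        s2 = transition(1, 0, c1)
        s3 = transition(2, s2, c2)
        return (self.value(1, 0, c1), self.value(2, s2, c2), self.value(3, s3, c3))


@dataclass(frozen=True)
class PredictionErrors:
    pe1: float
    pe2: float
    pe3: float


def softmax_policy(value_pair: tuple[float, float], beta: float) -> np.ndarray:
    """Two-option softmax p_i = exp(beta*V_i) / sum_j exp(beta*V_j)."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = beta * np.asarray(value_pair, dtype=float)
    z = z - z.max()  # overflow-safe
    e = np.exp(z)
    return e / e.sum()


def compute_prediction_errors(q: QTable, choices: tuple[int, int, int],
                              reward: int) -> PredictionErrors:
    v1, v2, v3 = q.chosen_values(*choices)
    return PredictionErrors(pe1=v2 - v1, pe2=v3 - v2, pe3=float(reward) - v3)


def update_values(q: QTable, choices: tuple[int, int, int], reward: int,
                  params: AgentParams) -> QTable:
    """One trial's value update; PEs taken from the pre-update table."""
    pe = compute_prediction_errors(q, choices, reward)
    c1, c2, c3 = choices
    s2 = transition(1, 0, c1)
    s3 = transition(2, s2, c2)
    out = q.copy()
    out.q[QTable.index(1, 0, c1)] += (params.alpha1 * pe.pe1
                                      + params.alpha1 * params.lam * pe.pe2
                                      + params.alpha1 * params.lam ** 2 * pe.pe3)
    out.q[QTable.index(2, s2, c2)] += (params.alpha2 * pe.pe2
                                       + params.alpha2 * params.lam * pe.pe3)
    out.q[QTable.index(3, s3, c3)] += params.alpha3 * pe.pe3
    return out


def trial_log_likelihood(q: QTable, choices: tuple[int, int, int],
                         params: AgentParams) -> float:
    """Log-probability of the three observed choices under the current table."""
    c1, c2, c3 = choices
    s2 = transition(1, 0, c1)
    s3 = transition(2, s2, c2)
    ll = 0.0
    for stage, state, a, beta in ((1, 0, c1, params.beta1),
                                  (2, s2, c2, params.beta2),
                                  (3, s3, c3, params.beta3)):
        pair = (q.value(stage, state, 0), q.value(stage, state, 1))
        ll += float(np.log(softmax_policy(pair, beta)[a]))
    return ll


# ---------------------------------------------------------------------------
# Compiled sequence kernels (arrays in, scalars/arrays out)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seq_pointwise(choices, rewards, new_block, params, q0, reset_per_block):
    """Per-trial log-likelihood of a time-ordered choice sequence.

    choices: (n, 3) int64; rewards: (n,) float64; new_block: (n,) bool;
    params: (7,) float64 ordered (a1, a2, a3, lam, b1, b2, b3).
    """
    n = choices.shape[0]
    a1, a2, a3, lam = params[0], params[1], params[2], params[3]
    b1, b2, b3 = params[4], params[5], params[6]
    q = np.full(N_Q, q0)
    out = np.empty(n)
    for t in range(n):
        if reset_per_block and new_block[t]:
            for k in range(N_Q):
                q[k] = q0
        c1 = choices[t, 0]
        c2 = choices[t, 1]
        c3 = choices[t, 2]
        s2 = c1
        s3 = 2 * c1 + c2
        i1 = c1
        i2 = 2 + 2 * s2 + c2
        i3 = 6 + 2 * s3 + c3
        ll = 0.0
        # stage 1
        d = b1 * (q[1 - c1] - q[c1])
        ll -= np.log1p(np.exp(d)) if d < 30.0 else d
        # stage 2
        base2 = 2 + 2 * s2
        d = b2 * (q[base2 + (1 - c2)] - q[base2 + c2])
        ll -= np.log1p(np.exp(d)) if d < 30.0 else d
        # stage 3
        base3 = 6 + 2 * s3
        d = b3 * (q[base3 + (1 - c3)] - q[base3 + c3])
        ll -= np.log1p(np.exp(d)) if d < 30.0 else d
        out[t] = ll
        # value update from pre-update table
        pe1 = q[i2] - q[i1]
        pe2 = q[i3] - q[i2]
        pe3 = rewards[t] - q[i3]
        q[i1] += a1 * pe1 + a1 * lam * pe2 + a1 * lam * lam * pe3
        q[i2] += a2 * pe2 + a2 * lam * pe3
        q[i3] += a3 * pe3
    return out


@njit(cache=True)
def _seq_loglik(choices, rewards, new_block, params, q0, reset_per_block):
    return np.sum(_seq_pointwise(choices, rewards, new_block, params, q0,
                                 reset_per_block))


@njit(cache=True)
def _replay_offered(choices, rewards, new_block, params, q0, reset_per_block):
    """Pre-update values of both offered actions per trial and stage.

    Returns (n, 3, 2): [trial, stage, action] value of the action pair
    offered at the visited state, just before the trial's update.
    """
    n = choices.shape[0]
    a1, a2, a3, lam = params[0], params[1], params[2], params[3]
    q = np.full(N_Q, q0)
    out = np.empty((n, 3, 2))
    for t in range(n):
        if reset_per_block and new_block[t]:
            for k in range(N_Q):
                q[k] = q0
        c1 = choices[t, 0]
        c2 = choices[t, 1]
        c3 = choices[t, 2]
        s2 = c1
        s3 = 2 * c1 + c2
        out[t, 0, 0] = q[0]
        out[t, 0, 1] = q[1]
        out[t, 1, 0] = q[2 + 2 * s2]
        out[t, 1, 1] = q[2 + 2 * s2 + 1]
        out[t, 2, 0] = q[6 + 2 * s3]
        out[t, 2, 1] = q[6 + 2 * s3 + 1]
        i1 = c1
        i2 = 2 + 2 * s2 + c2
        i3 = 6 + 2 * s3 + c3
        pe1 = q[i2] - q[i1]
        pe2 = q[i3] - q[i2]
        pe3 = rewards[t] - q[i3]
        q[i1] += a1 * pe1 + a1 * lam * pe2 + a1 * lam * lam * pe3
        q[i2] += a2 * pe2 + a2 * lam * pe3
        q[i3] += a3 * pe3
    return out


def _trial_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (choices, rewards, new_block) arrays from a trial table."""
    t = trials
    if "block" in t.columns:
        order_ok = (t.sort_values(["block", "trial"]).index == t.index).all() \
            if "trial" in t.columns else True
        if not order_ok:
            raise ValueError("trials must be time-ordered within participant")
        blocks = t["block"].to_numpy()
        new_block = np.empty(len(t), dtype=np.bool_)
        new_block[0] = True
        new_block[1:] = blocks[1:] != blocks[:-1]
    else:
        new_block = np.zeros(len(t), dtype=np.bool_)
        new_block[0] = True
    choices = t[["choice_s1", "choice_s2", "choice_s3"]].to_numpy(dtype=np.int64)
    rewards = t["reward"].to_numpy(dtype=float)
    return choices, rewards, new_block


def sequence_log_likelihood(trials: pd.DataFrame, params: AgentParams,
                            q0: float = Q_INIT,
                            reset_per_block: bool = False) -> float:
    """Total choice log-likelihood of one participant's ordered trials."""
    choices, rewards, new_block = _trial_arrays(trials)
    return float(_seq_loglik(choices, rewards, new_block, params.as_array(),
                             q0, reset_per_block))


def replay_q_values(trials: pd.DataFrame, params: AgentParams,
                    q0: float = Q_INIT,
                    reset_per_block: bool = False) -> np.ndarray:
    """Offered-action value pairs, (n_trials, 3 stages, 2 actions)."""
    choices, rewards, new_block = _trial_arrays(trials)
    return np.asarray(_replay_offered(choices, rewards, new_block,
                                      params.as_array(), q0, reset_per_block))


# ---------------------------------------------------------------------------
# Transformed (unconstrained) parameter scale used for population models
# ---------------------------------------------------------------------------
# alphas and lam live on a logit scale, betas on a log scale.

def params_to_natural(theta: np.ndarray) -> np.ndarray:
    """Map transformed 7-vectors (.., logit(alpha), .., log(beta)) to natural."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    from scipy.special import expit
    out[..., :4] = expit(theta[..., :4])
    out[..., 4:] = np.exp(theta[..., 4:])
    return out


def params_to_transformed(params: np.ndarray) -> np.ndarray:
    from scipy.special import logit
    params = np.asarray(params, dtype=float)
    out = np.empty_like(params)
    out[..., :4] = logit(np.clip(params[..., :4], 1e-9, 1 - 1e-9))
    out[..., 4:] = np.log(np.clip(params[..., 4:], 1e-12, None))
    return out


@dataclass(frozen=True)
class GroupParamDist:
    """Population distribution over AgentParams on the transformed scale.

    Individual effects are independent Normals: logit-normal for the
    learning rates and eligibility trace, log-normal for the decision
    temperatures. Defaults describe a moderately noisy, moderately fast
    learner population.
    """

    mean: np.ndarray  # (7,) transformed-scale means
    sd: np.ndarray    # (7,) transformed-scale sds

    @classmethod
    def default(cls) -> "GroupParamDist":
        mean = params_to_transformed(
            np.array([0.35, 0.35, 0.35, 0.6, 5.0, 5.0, 5.0]))
        sd = np.array([0.5, 0.5, 0.5, 0.5, 0.35, 0.35, 0.35])
        return cls(mean, sd)

    def shifted(self, **shifts: float) -> "GroupParamDist":
        """New distribution with named transformed-scale mean shifts
        (e.g. ``beta1=-0.8`` for a stage-1 temperature deficit)."""
        mean = self.mean.copy()
        for name, delta in shifts.items():
            mean[PARAM_NAMES.index(name)] += delta
        return GroupParamDist(mean, self.sd.copy())

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n draws of natural-scale 7-vectors."""
        theta = rng.normal(self.mean, self.sd, size=(n, 7))
        return params_to_natural(theta)


def simulate_agent(params: AgentParams, walk: RewardWalk, n_trials: int | None = None,
                   seed: int | np.random.Generator = 0, q0: float = Q_INIT,
                   reset_per_block: bool = False) -> pd.DataFrame:
    """Closed-loop simulation of one agent on a reward walk.

    Returns a trial table in the package schema plus latent columns
    ``q_s{k}_0 / q_s{k}_1`` (pre-update offered values) and
    ``absdq_s{k}`` per stage. Reaction times are not generated here; the
    cohort generator attaches them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = walk.n_trials if n_trials is None else n_trials
    if n > walk.n_trials:
        raise ValueError("n_trials exceeds reward-walk length")
    tpb = walk.trials_per_block
    q = QTable(q0)
    rows = []
    for t in range(n):
        block = t // tpb + 1
        trial = t % tpb + 1
        if reset_per_block and trial == 1:
            q = QTable(q0)
        # stage-wise softmax choices down the tree
        pair1 = (q.value(1, 0, 0), q.value(1, 0, 1))
        c1 = int(rng.random() < softmax_policy(pair1, params.beta1)[1])
        s2 = transition(1, 0, c1)
        pair2 = (q.value(2, s2, 0), q.value(2, s2, 1))
        c2 = int(rng.random() < softmax_policy(pair2, params.beta2)[1])
        s3 = transition(2, s2, c2)
        pair3 = (q.value(3, s3, 0), q.value(3, s3, 1))
        c3 = int(rng.random() < softmax_policy(pair3, params.beta3)[1])
        chest = transition(3, s3, c3)
        reward = int(rng.random() < walk.probs[t, chest])
        rows.append({
            "block": block, "trial": trial,
            "choice_s1": c1, "choice_s2": c2, "choice_s3": c3,
            "state_s2": s2, "state_s3": s3,
            "reward": reward,
            "q_s1_0": pair1[0], "q_s1_1": pair1[1],
            "q_s2_0": pair2[0], "q_s2_1": pair2[1],
            "q_s3_0": pair3[0], "q_s3_1": pair3[1],
            "absdq_s1": abs(pair1[1] - pair1[0]),
            "absdq_s2": abs(pair2[1] - pair2[0]),
            "absdq_s3": abs(pair3[1] - pair3[0]),
        })
        q = update_values(q, (c1, c2, c3), reward, params)
    return pd.DataFrame(rows)
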
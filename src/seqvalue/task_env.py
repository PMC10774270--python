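"""Three-stage deterministic tree task with drifting Bernoulli rewards.

The task is a binary tree of depth three: two houses, each leading
deterministically to one of two rooms (a pair of doors), each door leading
deterministically to a pair of chests. The eight terminal chests pay a
unit reward with probabilities that drift as bounded Gaussian random
walks, so the learner has to keep tracking value throughout a session.

State indexing convention used across the package:

* stage 1: a single root state; actions 0/1 pick the house.
* stage 2: states 0..1 (= house chosen); actions 0/1 pick the door.
* stage 3: states 0..3 (= 2*house + door); actions 0/1 pick the chest.
* chests:  0..7, with chest = 4*c1 + 2*c2 + c3 for the choice triple
  (c1, c2, c3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_CHESTS = 8
N_STAGES = 3


@dataclass
class TaskConfig:
    """Configuration of the task environment.

    Parameters
    ----------
    n_blocks, trials_per_block
        Session structure; the reward walk runs continuously across
        blocks, block boundaries only matter for data treatment.
    walk_sd
        Standard deviation of the per-trial Gaussian step of each chest's
        reward probability.
    walk_bounds
        (low, high) reflecting bounds of the walk, within [0, 1].
    init_probs
        Either an array of 8 starting probabilities inside the bounds, or
        None for uniform-random starts.
    seed
        Seed for the walk (and only the walk; outcome draws take their
        own generator).
    """

    n_blocks: int = 4
    trials_per_block: int = 50
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    init_probs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 <= low < high <= 1, got {self.walk_bounds}")
        if self.walk_sd < 0:
            raise ValueError(f"walk_sd must be >= 0, got {self.walk_sd}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if self.init_probs is not None:
            p = np.asarray(self.init_probs, dtype=float)
            if p.shape != (N_CHESTS,):
                raise ValueError(f"init_probs must have shape (8,), got {p.shape}")
            if np.any(p < lo) or np.any(p > hi):
                raise ValueError("init_probs must lie within walk_bounds")
            self.init_probs = p

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class RewardWalk:
    """Reward probabilities of the 8 chests over the session.

    ``probs`` has shape (n_trials, 8); row t gives the Bernoulli reward
    probability of each chest on (global) trial t.
    """

    probs: np.ndarray
    trials_per_block: int
    walk_bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_CHESTS:
            raise ValueError("probs must be a (n_trials, 8) matrix")

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def global_trial(self, block: int, trial: int) -> int:
        """Map 1-based (block, trial-within-block) to a row index."""
        t = (block - 1) * self.trials_per_block + (trial - 1)
        if not (0 <= t < self.n_trials):
            raise IndexError(f"(block={block}, trial={trial}) outside walk of {self.n_trials} trials")
        return t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, columns=[f"chest_{c}" for c in range(N_CHESTS)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trials_per_block: int,
                   walk_bounds: tuple[float, float] = (0.25, 0.75)) -> "RewardWalk":
        cols = [f"chest_{c}" for c in range(N_CHESTS)]
        return cls(df[cols].to_numpy(dtype=float), trials_per_block, walk_bounds)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (handles multiple bounces)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def make_reward_walk(config: TaskConfig) -> RewardWalk:
    """Simulate the reflected Gaussian random walk of chest probabilities."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.walk_bounds
    n = config.n_trials
    probs = np.empty((n, N_CHESTS))
    if config.init_probs is not None:
        probs[0] = config.init_probs
    else:
        probs[0] = rng.uniform(lo, hi, size=N_CHESTS)
    steps = rng.normal(0.0, config.walk_sd, size=(n - 1, N_CHESTS)) if n > 1 else None
    for t in range(1, n):
        probs[t] = _reflect(probs[t - 1] + steps[t - 1], lo, hi)
    return RewardWalk(probs, config.trials_per_block, config.walk_bounds)


def transition(stage: int, state: int, action: int) -> int:
    """Deterministic child of (stage, state) under a binary action.

    Returns the stage-2 state for stage 1, the stage-3 state for stage 2,
    and the chest index for stage 3.
    """
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action}")
    if stage == 1:
        if state != 0:
            raise ValueError("stage 1 has a single root state 0")
        return action
    if stage == 2:
        if state not in (0, 1):
            raise ValueError(f"invalid stage-2 state {state}")
        return 2 * state + action
    if stage == 3:
        if state not in (0, 1, 2, 3):
            raise ValueError(f"invalid stage-3 state {state}")
        return 2 * state + action
    raise ValueError(f"stage must be in {{1,2,3}}, got {stage}")


def chest_for_choices(c1: int, c2: int, c3: int) -> int:
    """Leaf reached by a full choice triple: 4*c1 + 2*c2 + c3."""
    s2 = transition(1, 0, c1)
    s3 = transition(2, s2, c2)
    return transition(3, s3, c3)


def chests_under(stage: int, state: int, action: int) -> np.ndarray:
    """Indices of the chests reachable by taking `action` in (stage, state)."""
    child = transition(stage, state, action)
    if stage == 1:
        return np.arange(4 * child, 4 * child + 4)
    if stage == 2:
        return np.arange(2 * child, 2 * child + 2)
    return np.array([child])


def draw_outcome(chest: int, trial: int, walk: RewardWalk, rng: np.random.Generator) -> int:
    """Bernoulli reward draw for a chest on a given global trial."""
    if not (0 <= chest < N_CHESTS):
        raise IndexError(f"chest must be in 0..7, got {chest}")
    if not (0 <= trial < walk.n_trials):
        raise IndexError(f"trial {trial} outside walk of {walk.n_trials} trials")
    return int(rng.random() < walk.probs[trial, chest])
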
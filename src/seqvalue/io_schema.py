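"""Trial-table schema, validation, exclusion rules and behaviour coding.

One row per participant-trial: three binary choices down the tree, the
states they imply, three stage reaction times in milliseconds, and the
terminal 0/1 reward. Data treatment removes the first trial of each
block, trials with any stage RT below 200 ms or above 4000 ms, and
trials whose feedback was not shown; participants are dropped when more
than 25% of their trials are excluded, more than 5% are no-responses,
or more than 5% lack feedback.

Accuracy and difficulty are coded against the task's true (drifting)
chest probabilities: at each stage the value of an offered option is the
best chest probability still reachable through it; a choice is correct
when the chosen option's value is at least the alternative's, and
difficulty is the absolute difference of the two option values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_env import RewardWalk, chests_under, transition

GROUPS = ("HC", "ADHD")

REQUIRED_COLUMNS = [
    "participant_id", "group", "block", "trial",
    "choice_s1", "choice_s2", "choice_s3",
    "state_s2", "state_s3",
    "rt_s1", "rt_s2", "rt_s3",
    "reward", "feedback_shown",
]

RT_MIN_MS = 200.0
RT_MAX_MS = 4000.0
MAX_EXCLUDED_FRACTION = 0.25
MAX_NO_RESPONSE_FRACTION = 0.05
MAX_MISSING_FEEDBACK_FRACTION = 0.05


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """Row-level contents violate the schema."""


@dataclass
class ExclusionReport:
    n_trials_removed_first: int = 0
    n_trials_removed_rt: int = 0
    n_trials_removed_feedback: int = 0
    fraction_removed: float = 0.0
    participants_dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_trials_removed(self) -> int:
        return (self.n_trials_removed_first + self.n_trials_removed_rt
                + self.n_trials_removed_feedback)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table in place; raises with offending row numbers."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise ValidationError(
            f"group must be one of {GROUPS}; bad rows: {list(df.index[bad_group][:5])}")
    for col in ("choice_s1", "choice_s2", "choice_s3"):
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1])
        if bad.any():
            raise ValidationError(
                f"{col} must be 0/1 or missing; bad rows: {list(df.index[bad][:5])}")
    bad_reward = ~df["reward"].isin([0, 1])
    if bad_reward.any():
        raise ValidationError(
            f"reward must be 0 or 1; bad rows: {list(df.index[bad_reward][:5])}")
    # tree-transition consistency on complete rows
    complete = df[["choice_s1", "choice_s2"]].notna().all(axis=1)
    sub = df.loc[complete]
    exp_s2 = sub["choice_s1"].astype(int)
    exp_s3 = 2 * exp_s2 + sub["choice_s2"].astype(int)
    bad_tree = (sub["state_s2"].astype(int) != exp_s2) | (sub["state_s3"].astype(int) != exp_s3)
    if bad_tree.any():
        raise ValidationError(
            f"state ids violate the deterministic tree; bad rows: {list(sub.index[bad_tree][:5])}")
    return df


def load_trials(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trial CSV, optionally renaming columns, and validate it.

    ``schema`` maps file column names to the canonical names in
    ``REQUIRED_COLUMNS``.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    if "feedback_shown" in df.columns:
        df["feedback_shown"] = df["feedback_shown"].astype(bool)
    return validate_trials(df)


def save_trials(df: pd.DataFrame, path) -> None:
    validate_trials(df)
    df.to_csv(path, index=False)


def _trial_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial exclusion flags, attributed in rule order."""
    first = df["trial"] == 1
    rt = df[["rt_s1", "rt_s2", "rt_s3"]]
    no_response = (rt.isna().any(axis=1)
                   | df[["choice_s1", "choice_s2", "choice_s3"]].isna().any(axis=1))
    bad_rt = no_response | (rt < RT_MIN_MS).any(axis=1) | (rt > RT_MAX_MS).any(axis=1)
    no_feedback = ~df["feedback_shown"].astype(bool)
    return pd.DataFrame({
        "excl_first": first,
        "excl_rt": ~first & bad_rt,
        "excl_feedback": ~first & ~bad_rt & no_feedback,
        "no_response": no_response,
        "no_feedback": no_feedback,
    }, index=df.index)


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the data-treatment rules; idempotent.

    Trial-level removals in order: first trial of each block, RT outside
    [200, 4000] ms (including no-responses), missing feedback.
    Participant-level rules use pre-removal denominators (all of the
    participant's trials).
    """
    report = ExclusionReport()
    if len(df) == 0:
        return df.copy(), report
    validate_trials(df)
    flags = _trial_flags(df)
    report.n_trials_removed_first = int(flags["excl_first"].sum())
    report.n_trials_removed_rt = int(flags["excl_rt"].sum())
    report.n_trials_removed_feedback = int(flags["excl_feedback"].sum())
    excluded = flags[["excl_first", "excl_rt", "excl_feedback"]].any(axis=1)
    report.fraction_removed = float(excluded.mean())

    for pid, idx in df.groupby("participant_id").groups.items():
        f = flags.loc[idx]
        n = len(idx)
        frac_excl = f[["excl_first", "excl_rt", "excl_feedback"]].any(axis=1).mean()
        if frac_excl > MAX_EXCLUDED_FRACTION:
            report.participants_dropped.append((str(pid), "excluded_trials"))
        elif f["no_response"].mean() > MAX_NO_RESPONSE_FRACTION:
            report.participants_dropped.append((str(pid), "no_response"))
        elif f["no_feedback"].mean() > MAX_MISSING_FEEDBACK_FRACTION:
            report.participants_dropped.append((str(pid), "missing_feedback"))

    dropped_ids = {pid for pid, _ in report.participants_dropped}
    keep = ~excluded & ~df["participant_id"].astype(str).isin(dropped_ids)
    return df.loc[keep].copy(), report


def option_values(walk: RewardWalk, block: int, trial: int,
                  stage: int, state: int, mode: str = "max") -> np.ndarray:
    """True expected value of both options offered at (stage, state).

    The value of an option is the max (default) or mean of the true
    chest probabilities reachable through it on that trial.
    """
    t = walk.global_trial(int(block), int(trial))
    agg = np.max if mode == "max" else np.mean
    return np.array([agg(walk.probs[t, chests_under(stage, state, a)])
                     for a in (0, 1)])


def code_accuracy_difficulty(df: pd.DataFrame, walk: RewardWalk,
                             option_value: str = "max") -> pd.DataFrame:
    """Code per-stage correctness and difficulty against the true walk.

    Ties (both options' best completions exactly equal) are coded
    correct. Returns a frame aligned with ``df`` holding
    correct_s{1,2,3} and difficulty_s{1,2,3}.
    """
    if option_value not in ("max", "mean"):
        raise ValueError("option_value must be 'max' or 'mean'")
    out = {}
    for k in (1, 2, 3):
        out[f"correct_s{k}"] = np.empty(len(df), dtype=int)
        out[f"difficulty_s{k}"] = np.empty(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        states = (0, int(row["state_s2"]), int(row["state_s3"]))
        choices = (int(row["choice_s1"]), int(row["choice_s2"]), int(row["choice_s3"]))
        for k in (1, 2, 3):
            v = option_values(walk, row["block"], row["trial"], k,
                              states[k - 1], option_value)
            c = choices[k - 1]
            out[f"correct_s{k}"][i] = int(v[c] >= v[1 - c])
            out[f"difficulty_s{k}"][i] = abs(v[1] - v[0])
    return pd.DataFrame(out, index=df.index)
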
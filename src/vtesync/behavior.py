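"""Delayed-alternation choice scoring and session-level behavioral metrics.

The task rewards choosing the goal arm opposite the previous trial's
choice.  This module scores per-trial correctness under that rule and
computes the session metrics used to characterize the behavior:

* perseveration — repeated (3x) selection of the same arm, scored over
  overlapping triples: a run of 10 lefts then 10 rights gives 16 of 18
  all-equal windows, i.e. 89% perseveration while turn bias is 0%;
* turn bias — |#left - #right| / #trials, a lateral preference index;
* VTE/non-VTE overlap with perseverative error sequences;
* choice accuracy split by VTE class;
* the normalized difference score (Y - X)/(Y + X) used for per-subject
  condition contrasts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .defaults import MIN_TRIALS_PER_CLASS

__all__ = [
    "Condition",
    "Epoch",
    "TrialRecord",
    "SessionBehaviorSummary",
    "score_alternation",
    "perseveration_score",
    "turn_bias",
    "vte_error_overlap",
    "norm_diff",
    "accuracy_by_class",
    "summarize_session",
]

ARMS = ("L", "R")


class Condition(str, Enum):
    NO_INFUSION = "no_infusion"
    SALINE = "saline"
    MUSCIMOL = "muscimol"


class Epoch(str, Enum):
    BASELINE = "baseline"
    TESTING = "testing"


@dataclass
class TrialRecord:
    trial_index: int
    arm: str
    correct: bool
    is_vte: bool
    epoch: Epoch = Epoch.BASELINE
    condition: Condition = Condition.NO_INFUSION


@dataclass
class SessionBehaviorSummary:
    pct_correct_overall: float
    pct_correct_vte: float | None
    pct_correct_nonvte: float | None
    perseveration_score: float
    turn_bias: float
    n_trials: int
    n_vte: int


def _check_arms(arms) -> list[str]:
    arms = list(arms)
    if any(a not in ARMS for a in arms):
        bad = sorted({a for a in arms if a not in ARMS})
        raise ValueError(f"arm labels must be 'L' or 'R', got {bad}")
    return arms


def score_alternation(arms) -> np.ndarray:
    """Per-trial correctness under the alternation rule.

    Trial t (t >= 2) is correct iff its arm differs from trial t-1's; the
    first trial is a free choice, rewarded either way, and scored correct.
    """
    arms = _check_arms(arms)
    if len(arms) < 1:
        raise ValueError("need at least one trial")
    correct = np.ones(len(arms), dtype=bool)
    for t in range(1, len(arms)):
        correct[t] = arms[t] != arms[t - 1]
    return correct


def perseveration_score(arms) -> float:
    """Percentage of overlapping 3-trial windows with all-equal arm choices.

    One count of perseveration is three consecutive same-arm choices
    (two consecutive alternation errors); with n trials there are n-2
    overlapping windows.
    """
    arms = _check_arms(arms)
    n = len(arms)
    if n < 3:
        raise ValueError("perseveration undefined for fewer than 3 trials")
    hits = sum(arms[i] == arms[i + 1] == arms[i + 2] for i in range(n - 2))
    return 100.0 * hits / (n - 2)


def turn_bias(arms) -> float:
    """|#left - #right| / #trials as a percentage."""
    arms = _check_arms(arms)
    if len(arms) < 1:
        raise ValueError("need at least one trial")
    n_left = arms.count("L")
    return 100.0 * abs(n_left - (len(arms) - n_left)) / len(arms)


def _perseverative_runs(arms: list[str]) -> list[tuple[int, int]]:
    """Maximal runs of >= 3 identical consecutive arms, as (start, length)."""
    runs = []
    i = 0
    n = len(arms)
    while i < n:
        j = i
        while j + 1 < n and arms[j + 1] == arms[i]:
            j += 1
        if j - i + 1 >= 3:
            runs.append((i, j - i + 1))
        i = j + 1
    return runs


def vte_error_overlap(trials: list[TrialRecord]) -> dict[str, float | None]:
    """Share of perseverative error sequences whose first error was a VTE.

    Each maximal run of >= 3 same-arm choices is one perseverative event;
    its first choice error (the second trial of the run) is the point
    where the future error became committed.  Returns, separately for VTE
    and non-VTE, 100 x (first-errors of that class) / (perseverative
    events).  With no perseverative events both values are None.
    """
    arms = _check_arms([t.arm for t in trials])
    runs = _perseverative_runs(arms)
    if not runs:
        warnings.warn("no perseverative events: overlap undefined", stacklevel=2)
        return {"vte": None, "non_vte": None}
    n_vte = n_non = 0
    for start, _length in runs:
        first_error = trials[start + 1]
        if first_error.is_vte:
            n_vte += 1
        else:
            n_non += 1
    total = len(runs)
    return {"vte": 100.0 * n_vte / total, "non_vte": 100.0 * n_non / total}


def norm_diff(y: float, x: float) -> float:
    """Normalized difference score (y - x)/(y + x), bounded in [-1, 1].

    Used per subject to contrast two conditions while removing
    between-subject scale differences; undefined when y + x = 0.
    """
    if y < 0 or x < 0:
        raise ValueError("norm_diff expects nonnegative inputs")
    denom = y + x
    if denom == 0:
        raise ValueError("norm_diff undefined: y + x = 0")
    return (y - x) / denom


def accuracy_by_class(
    trials: list[TrialRecord], min_trials: int = MIN_TRIALS_PER_CLASS
) -> dict[str, float | None]:
    """% correct within the VTE and non-VTE trial subsets.

    Subsets with fewer than ``min_trials`` trials (default 2) are reported
    as missing rather than as an unstable percentage.
    """
    out: dict[str, float | None] = {}
    for key, want_vte in (("vte", True), ("non_vte", False)):
        subset = [t for t in trials if t.is_vte == want_vte]
        if len(subset) < min_trials:
            out[key] = None
        else:
            out[key] = 100.0 * sum(t.correct for t in subset) / len(subset)
    return out


def summarize_session(trials: list[TrialRecord]) -> SessionBehaviorSummary:
    """All session-level behavioral metrics from a scored trial list."""
    arms = [t.arm for t in trials]
    acc = accuracy_by_class(trials)
    return SessionBehaviorSummary(
        pct_correct_overall=100.0 * sum(t.correct for t in trials) / len(trials),
        pct_correct_vte=acc["vte"],
        pct_correct_nonvte=acc["non_vte"],
        perseveration_score=perseveration_score(arms),
        turn_bias=turn_bias(arms),
        n_trials=len(trials),
        n_vte=sum(t.is_vte for t in trials),
    )
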
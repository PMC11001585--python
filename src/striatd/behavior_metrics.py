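"""Behavioral summary statistics for rule-switch sessions.

Operates on tidy trial tables (one row per trial) with at least the
columns ``cue_location``, ``cue_frequency``, ``choice`` and ``correct``
(optionally ``miss``).  Provides session accuracy, the response-bias
index, novice/intermediate/expert staging, the acquisition criterion,
learning-rate slopes, post-hoc session truncation and stay/switch
performance splits.

Staging: novice < 60% correct; intermediate 60-80%; expert at least 80%
overall *and* at least 60% in each of the four conditions — identical to
the task-acquisition criterion, so a criterion session is always an
expert session (sessions above 80% overall that fail a condition clause
are classed intermediate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .task_env import CONDITIONS, classify_stay_switch, correct_action

STAGE_NOVICE_BELOW = 0.60
STAGE_EXPERT_OVERALL = 0.80
STAGE_EXPERT_PER_CONDITION = 0.60


@dataclass(frozen=True)
class SessionSummary:
    fraction_correct: float
    per_condition: Mapping[str, float]
    response_bias: float
    abs_response_bias: float
    stage: str
    n_trials: int


def _select(trials: pd.DataFrame, filter: Mapping | None) -> pd.DataFrame:
    if not filter:
        return trials
    mask = np.ones(len(trials), dtype=bool)
    for col, val in filter.items():
        mask &= trials[col].to_numpy() == val
    return trials.loc[mask]


def fraction_correct(trials: pd.DataFrame, filter: Mapping | None = None) -> float:
    """Fraction of correct trials, optionally over a column-equality subset.

    An empty selection yields NaN (undefined), never zero.
    """
    sel = _select(trials, filter)
    if len(sel) == 0:
        return float("nan")
    return float(np.mean(sel["correct"].to_numpy(dtype=float)))


def per_condition_fractions(trials: pd.DataFrame) -> dict[str, float]:
    return {
        c.label: fraction_correct(
            trials, {"cue_location": c.cue_location, "cue_frequency": c.cue_frequency})
        for c in CONDITIONS
    }


# ---------------------------------------------------------------------------
# Response bias
# ---------------------------------------------------------------------------

def response_bias(trials: pd.DataFrame, formula: str = "ratio") -> float:
    """Side-preference index from per-side accuracies.

    fcl / fcr are the fractions correct among left-cued / right-cued
    trials.  The default "ratio" form ``fcl / (fcl + fcr)`` is 0.5 for
    unbiased behavior and 0 or 1 for a one-sided responder, so the
    absolute bias ``|bias - 0.5|`` spans [0, 0.5] as intended.  The
    "printed" variant ``(fcl - fcr) / fcl`` is retained for reference but
    does not respect that range.
    """
    fcl = fraction_correct(trials, {"cue_location": "left"})
    fcr = fraction_correct(trials, {"cue_location": "right"})
    if not (np.isfinite(fcl) and np.isfinite(fcr)):
        return float("nan")
    if formula == "ratio":
        denom = fcl + fcr
        return float(fcl / denom) if denom > 0 else float("nan")
    if formula == "printed":
        return float((fcl - fcr) / fcl) if fcl > 0 else float("nan")
    raise ValueError(f"unknown response-bias formula {formula!r}")


def abs_response_bias(trials: pd.DataFrame, formula: str = "ratio") -> float:
    """|bias - 0.5|; 0 for unbiased, 0.5 for a one-sided responder."""
    bias = response_bias(trials, formula=formula)
    return float(abs(bias - 0.5)) if np.isfinite(bias) else float("nan")


# ---------------------------------------------------------------------------
# Staging and criterion
# ---------------------------------------------------------------------------

def meets_criterion_fractions(overall: float, per_condition: Iterable[float]) -> bool:
    per_condition = [p for p in per_condition if np.isfinite(p)]
    return (
        np.isfinite(overall)
        and overall >= STAGE_EXPERT_OVERALL
        and len(per_condition) == 4
        and all(p >= STAGE_EXPERT_PER_CONDITION for p in per_condition)
    )


def stage_from_fractions(overall: float, per_condition: Iterable[float]) -> str:
    if not np.isfinite(overall):
        return "undefined"
    if overall < STAGE_NOVICE_BELOW:
        return "novice"
    if meets_criterion_fractions(overall, per_condition):
        return "expert"
    return "intermediate"


def summarize_session(trials: pd.DataFrame) -> SessionSummary:
    overall = fraction_correct(trials)
    per_cond = per_condition_fractions(trials)
    bias = response_bias(trials)
    return SessionSummary(
        fraction_correct=overall,
        per_condition=per_cond,
        response_bias=bias,
        abs_response_bias=float(abs(bias - 0.5)) if np.isfinite(bias) else float("nan"),
        stage=stage_from_fractions(overall, per_cond.values()),
        n_trials=len(trials),
    )


def stage_session(summary: SessionSummary | pd.DataFrame) -> str:
    if isinstance(summary, pd.DataFrame):
        summary = summarize_session(summary)
    return summary.stage


def meets_criterion(summary: SessionSummary | pd.DataFrame) -> bool:
    if isinstance(summary, pd.DataFrame):
        summary = summarize_session(summary)
    return meets_criterion_fractions(summary.fraction_correct, summary.per_condition.values())


# ---------------------------------------------------------------------------
# Learning rate
# ---------------------------------------------------------------------------

def _slope(y: Sequence[float]) -> float:
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return float("nan")
    x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def learning_rate(per_session_accuracy: Sequence[float], rule: str,
                  stages: Sequence[str] | None = None):
    """Learning-rate slope(s) of the per-session performance curve.

    Least-squares slope from the first session to the first criterion
    session (fraction correct per session).  For the initial *location*
    rule two fits are returned — first session to last novice session, and
    first intermediate session to the first criterion session — to capture
    the slope increase after the strongly biased novice phase.  ``stages``
    may supply precomputed stage labels; otherwise they are derived from
    the overall accuracies alone.  Segments shorter than two sessions give
    NaN.
    """
    acc = np.asarray(per_session_accuracy, dtype=float)
    if stages is None:
        stages = [
            "novice" if a < STAGE_NOVICE_BELOW
            else ("expert" if a >= STAGE_EXPERT_OVERALL else "intermediate")
            for a in acc
        ]
    stages = list(stages)
    expert_idx = [i for i, s in enumerate(stages) if s == "expert"]
    first_crit = expert_idx[0] if expert_idx else len(acc) - 1
    if rule != "location":
        return _slope(acc[: first_crit + 1])
    novice_idx = [i for i, s in enumerate(stages) if s == "novice"]
    inter_idx = [i for i, s in enumerate(stages) if s == "intermediate"]
    last_novice = novice_idx[-1] if novice_idx else -1
    first_inter = inter_idx[0] if inter_idx else (last_novice + 1)
    slope1 = _slope(acc[: last_novice + 1])
    slope2 = _slope(acc[first_inter: first_crit + 1])
    return slope1, slope2


# ---------------------------------------------------------------------------
# Session truncation
# ---------------------------------------------------------------------------

def truncate_session(trials: pd.DataFrame, window: int = 20,
                     sd_factor: float = 1.5) -> pd.DataFrame:
    """Post-hoc session truncation at satiety.

    Drops trials from the first miss occurring after 90% of the session,
    then further drops a trailing stretch of the last 15% of trials whose
    running performance (fraction correct in ``window``-trial windows)
    falls below the session mean minus ``sd_factor`` standard deviations of
    the windowed performance.  Never removes more than a further 15%.
    """
    df = trials.reset_index(drop=True)
    n = len(df)
    if n == 0:
        return df
    if "miss" in df.columns:
        miss_pos = np.flatnonzero(df["miss"].to_numpy(dtype=bool))
        late = miss_pos[miss_pos >= int(np.ceil(0.9 * n))]
        if late.size:
            df = df.iloc[: late[0]].reset_index(drop=True)
    m = len(df)
    if m < 2 * window:
        return df
    acc = (
        pd.Series(df["correct"].to_numpy(dtype=float))
        .rolling(window, min_periods=window)
        .mean()
        .to_numpy()
    )
    valid = ~np.isnan(acc)
    mu = float(np.nanmean(acc))
    sd = float(np.nanstd(acc))
    if sd == 0:
        return df
    threshold = mu - sd_factor * sd
    tail_floor = int(np.ceil(0.85 * m))
    below = np.flatnonzero(valid & (acc < threshold))
    below = below[below >= tail_floor]
    if below.size:
        cut = max(int(below[0]) - window + 1, tail_floor)
        df = df.iloc[:cut].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Stay / switch splits
# ---------------------------------------------------------------------------

def stay_switch_performance(trials: pd.DataFrame, prev_rule: str, rule: str,
                            first_n: int = 100) -> dict[str, float]:
    """Fraction correct in stay vs switch conditions over the first ``first_n`` trials.

    Apply to the last session of the previous rule and to the rule-switch
    session to quantify perseveration; conditions are classified by
    whether their correct response survives the ``prev_rule`` -> ``rule``
    change.
    """
    head = trials.reset_index(drop=True).iloc[:first_n]
    labels = [
        classify_stay_switch(
            prev_rule, rule,
            next(c for c in CONDITIONS
                 if c.cue_location == row.cue_location and c.cue_frequency == row.cue_frequency))
        for row in head.itertuples()
    ]
    out: dict[str, float] = {}
    arr = head["correct"].to_numpy(dtype=float)
    for cls in ("stay", "switch"):
        mask = np.array([lab == cls for lab in labels])
        out[cls] = float(arr[mask].mean()) if mask.any() else float("nan")
    return out
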
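"""Per-participant outcome measures.

Accuracy is the mean angular endpoint error over the valid experimental
trials of a condition; precision is the sample standard deviation of those
errors (trial-to-trial dispersion); reach time is averaged after removing
trials more than 3 SD from the participant's own mean.  The outlier filter
applies only to reach-time analyses, never to error analyses, and the
abbreviated-protocol subset keeps the first n trials of each condition in
presentation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingConditionError
from .simulate import SessionLog

__all__ = [
    "ConditionSummary",
    "ParticipantSummary",
    "SlopeResult",
    "remove_time_outliers",
    "summarize_participant",
    "error_slope",
    "summaries_table",
]


@dataclass(frozen=True)
class ConditionSummary:
    """One participant x condition cell of the outcome table."""

    mean_error_deg: float
    sd_error_deg: float
    mean_reach_time_ms: float
    n_trials: int
    n_time_outliers_removed: int


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    first_n: int | None  # None = all trials
    by_condition: Mapping[str, ConditionSummary]


@dataclass(frozen=True)
class SlopeResult:
    """OLS fit of error (deg) on within-condition 0-based trial order."""

    slope: float  # deg / trial
    intercept: float
    n: int


def remove_time_outliers(
    times_ms: Sequence[float], k: float = 3.0
) -> tuple[np.ndarray, int]:
    """Drop reach times more than ``k`` SD from the mean (single pass).

    The mean and SD are computed once on the full input; values with
    ``|t - mean| > k * SD`` are removed.  With zero SD the input is returned
    unchanged.
    """
    t = np.asarray(times_ms, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 reach times")
    sd = float(np.std(t, ddof=1))
    if sd == 0.0:
        return t.copy(), 0
    keep = np.abs(t - t.mean()) <= k * sd
    return t[keep], int(t.size - keep.sum())


def summarize_participant(
    log: SessionLog, first_n: int | None = None
) -> ParticipantSummary:
    """Accuracy, precision and mean reach time per condition.

    Practice trials and invalid trials are excluded.  Precision uses the
    n-1 denominator.  ``first_n`` restricts each condition to its first n
    valid trials in presentation order before any computation, mirroring an
    abbreviated run of the protocol.
    """
    out: dict[str, ConditionSummary] = {}
    for condition in log.protocol.conditions:
        trials = log.condition_trials(condition, valid_only=True, first_n=first_n)
        if not trials:
            raise MissingConditionError(
                f"participant {log.participant_id!r} has no valid "
                f"{condition!r} trials"
            )
        errors = np.array([t.error_deg for t in trials])
        times = np.array([t.reach_time_ms for t in trials])
        if times.size >= 2:
            kept, n_removed = remove_time_outliers(times)
        else:
            kept, n_removed = times, 0
        out[condition] = ConditionSummary(
            mean_error_deg=float(errors.mean()),
            sd_error_deg=float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0,
            mean_reach_time_ms=float(kept.mean()),
            n_trials=int(errors.size),
            n_time_outliers_removed=n_removed,
        )
    return ParticipantSummary(
        participant_id=log.participant_id, first_n=first_n, by_condition=out
    )


def error_slope(
    log: SessionLog, condition: str, first_n: int | None = None
) -> SlopeResult:
    """Change of error across the experiment: OLS slope in deg/trial.

    The regressor is the 0-based within-condition presentation index (the
    two conditions are interleaved, so within-condition order is the natural
    time axis for a per-condition slope).
    """
    trials = log.condition_trials(condition, valid_only=True, first_n=first_n)
    if len(trials) < 3:
        raise InsufficientDataError(
            f"need >= 3 trials for a slope, got {len(trials)}"
        )
    y = np.array([t.error_deg for t in trials])
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    slope = float((xc @ y) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    return SlopeResult(slope=slope, intercept=intercept, n=int(y.size))


def summaries_table(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    """Long-format table: one row per participant x condition."""
    rows = []
    for s in summaries:
        for condition, c in s.by_condition.items():
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": condition,
                    "first_n": "all" if s.first_n is None else s.first_n,
                    "mean_error_deg": c.mean_error_deg,
                    "sd_error_deg": c.sd_error_deg,
                    "mean_reach_time_ms": c.mean_reach_time_ms,
                    "n_trials": c.n_trials,
                    "n_time_outliers_removed": c.n_time_outliers_removed,
                }
            )
    return pd.DataFrame(rows)
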
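"""The inferential battery for reaching sessions.

Condition contrasts use rank tests with the tie-corrected normal
approximation and no continuity correction (the convention of mainstream
commercial statistics packages, whose output these tests mirror): the
Wilcoxon signed-rank test for paired group designs and the Mann-Whitney U
test for individual-level designs.  Slopes of error against trial order are
tested with one-sample t tests at the group level and with a shuffle
permutation null (resampling trials without replacement, which preserves the
error distribution while destroying temporal order) at the individual level.
A Shapiro-Wilk normality gate is reported as a diagnostic but does not
switch test families.

Sign conventions: the signed-rank statistic T is the sum of positive ranks
of ``second - first``; U is reported for the second-listed group, with the
first-group orientation exposed alongside (``U_first + U_second = n1*n2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateStatisticError,
    InsufficientDataError,
    NoInformationError,
)
from .metrics import (
    ParticipantSummary,
    error_slope,
    remove_time_outliers,
    summaries_table,
    summarize_participant,
)
from .simulate import SessionLog

__all__ = [
    "StatResult",
    "PermutationResult",
    "StatReport",
    "shapiro_wilk",
    "wilcoxon_paired",
    "mann_whitney",
    "pearson_corr",
    "one_sample_t",
    "permutation_slope_test",
    "analyze_experiment",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test.

    ``statistic`` is the headline value named by ``statistic_name`` (T, U,
    W, r or t); ``z`` is the normal-approximation deviate where applicable;
    ``p`` is two-sided.  ``details`` carries secondary quantities (both
    statistic orientations, tie counts, degrees of freedom, ...).
    """

    test: str
    statistic_name: str
    statistic: float
    p: float
    n: int | tuple[int, ...]
    z: float | None = None
    details: Mapping[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "test": self.test,
            "statistic_name": self.statistic_name,
            "statistic": _f(self.statistic),
            "z": None if self.z is None else _f(self.z),
            "p": _f(self.p),
            "n": self.n if isinstance(self.n, int) else list(self.n),
            "details": {k: _f(v) for k, v in self.details.items()},
        }


@dataclass(frozen=True)
class PermutationResult:
    """Shuffle-null test of an observed error-vs-trial slope."""

    observed_slope: float
    n_permutations: int
    p: float
    seed: int | None
    n: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "test": "permutation_slope",
            "observed_slope": _f(self.observed_slope),
            "n_permutations": self.n_permutations,
            "p": _f(self.p),
            "seed": self.seed,
            "n": self.n,
        }


def _f(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def shapiro_wilk(values: Sequence[float]) -> StatResult:
    """Shapiro-Wilk normality test (W and p, standard approximation)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}"
        )
    if np.ptp(v) == 0.0:
        raise DegenerateStatisticError("constant input to Shapiro-Wilk")
    w, p = sps.shapiro(v)
    return StatResult(
        test="shapiro_wilk",
        statistic_name="W",
        statistic=float(w),
        p=float(p),
        n=int(v.size),
    )


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Related-samples Wilcoxon signed-rank test, tie-corrected normal z.

    Differences are ``y - x``; zero differences are dropped; ranks of the
    absolute differences use midranks for ties.  ``T`` is the sum of ranks
    of positive differences,

        z = (T - n(n+1)/4) / sigma_T,
        sigma_T^2 = n(n+1)(2n+1)/24 - sum(t^3 - t)/48,

    summing over tie groups of the absolute differences, with no continuity
    correction; p is the two-sided normal tail.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    d = yv - xv
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        raise NoInformationError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    t_pos = float(ranks[d > 0].sum())
    t_neg = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateStatisticError("zero variance in signed-rank null")
    z = (t_pos - mu) / math.sqrt(var)
    return StatResult(
        test="wilcoxon_signed_rank",
        statistic_name="T",
        statistic=t_pos,
        z=z,
        p=_two_sided_normal_p(z),
        n=n,
        details={
            "T_positive": t_pos,
            "T_negative": t_neg,
            "n_zero_dropped": int(xv.size - n),
            "n_tie_groups": int((counts > 1).sum()),
            "sigma_T": math.sqrt(var),
        },
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Independent-samples Mann-Whitney U test, tie-corrected normal z.

    ``U`` (the headline statistic) counts pairs where a ``y`` value exceeds
    an ``x`` value, ties counting one half; the first-group orientation is
    exposed in ``details``.

        z = (U - n1 n2 / 2) / sigma_U,
        sigma_U^2 = n1 n2 / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1))),

    with no continuity correction; p is the two-sided normal tail.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n1, n2 = int(xv.size), int(yv.size)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both groups must be nonempty")
    combined = np.concatenate([xv, yv])
    ranks = sps.rankdata(combined)
    r2 = float(ranks[n1:].sum())
    u_second = r2 - n2 * (n2 + 1) / 2.0
    u_first = n1 * n2 - u_second
    mu = n1 * n2 / 2.0
    big_n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        raise DegenerateStatisticError("all observations tied; U has no variance")
    z = (u_second - mu) / math.sqrt(var)
    return StatResult(
        test="mann_whitney_u",
        statistic_name="U",
        statistic=u_second,
        z=z,
        p=_two_sided_normal_p(z),
        n=(n1, n2),
        details={
            "U_second": u_second,
            "U_first": u_first,
            "rank_sum_second": r2,
            "n_tie_groups": int((counts > 1).sum()),
            "sigma_U": math.sqrt(var),
        },
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson product-moment correlation with the exact t-based p value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.size < 3:
        raise InsufficientDataError("need equal-length sequences with n >= 3")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise DegenerateStatisticError("zero variance input to correlation")
    n = int(xv.size)
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t, p = math.copysign(math.inf, r), 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        test="pearson_correlation",
        statistic_name="r",
        statistic=r,
        p=p,
        n=n,
        details={"t": t, "df": df},
    )


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> StatResult:
    """One-sample two-sided t test of the mean against ``mu0``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need n >= 2 for a t test")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DegenerateStatisticError("zero standard deviation in t test")
    n = int(v.size)
    t = (float(v.mean()) - mu0) / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return StatResult(
        test="one_sample_t",
        statistic_name="t",
        statistic=t,
        p=p,
        n=n,
        details={"mean": float(v.mean()), "sd": sd, "df": n - 1, "mu0": mu0},
    )


def permutation_slope_test(
    errors: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Shuffle-null test of the error-vs-trial slope.

    Each permutation resamples the error sequence without replacement (a
    full reshuffle), recomputes the OLS slope on the 0-based trial index,
    and the two-sided p value is the add-one-corrected proportion of
    permuted |slopes| at least as large as the observed:

        p = (1 + #{|s*| >= |s_obs|}) / (n_permutations + 1).

    A constant series has p = 1 (every permuted slope equals the observed 0).
    """
    y = np.asarray(errors, dtype=float)
    if y.size < 3:
        raise InsufficientDataError("need >= 3 trials for a slope permutation test")
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    observed = float(xc @ y) / sxx
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perms = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)
    slopes = perms @ xc / sxx
    count = int(np.count_nonzero(np.abs(slopes) >= abs(observed) - 1e-12))
    p = (1.0 + count) / (n_permutations + 1.0)
    used_seed = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationResult(
        observed_slope=observed,
        n_permutations=n_permutations,
        p=p,
        seed=None if used_seed is None else int(used_seed),
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------


@dataclass
class StatReport:
    """The complete battery for one experiment.

    ``tests`` holds group-level results (paired design); ``per_participant``
    holds the individual-level battery (one entry per participant).  The
    first-25 accuracy contrast is always repeated under key
    ``accuracy_first25_*``.  ``normality`` is diagnostic only.
    """

    experiment: str
    design: str
    conditions: tuple[str, str]
    n_participants: int
    first_n: int | None
    summaries: pd.DataFrame
    group: dict[str, dict[str, float]]
    group_first25: dict[str, dict[str, float]]
    normality: dict[str, StatResult]
    tests: dict[str, StatResult]
    slopes: dict[str, dict[str, float]]
    per_participant: dict[str, dict[str, StatResult | PermutationResult]]
    n_tests: int
    seed: int | None

    def to_dict(self) -> dict[str, Any]:
        return {
            "experiment": self.experiment,
            "design": self.design,
            "conditions": list(self.conditions),
            "n_participants": self.n_participants,
            "first_n": self.first_n,
            "summaries": self.summaries.to_dict(orient="records"),
            "group": self.group,
            "group_first25": self.group_first25,
            "normality": {k: v.to_dict() for k, v in self.normality.items()},
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
            "slopes": self.slopes,
            "per_participant": {
                pid: {k: v.to_dict() for k, v in battery.items()}
                for pid, battery in self.per_participant.items()
            },
            "n_tests": self.n_tests,
            "seed": self.seed,
        }


def _group_stats(
    summaries: Sequence[ParticipantSummary], conditions: tuple[str, str]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for c in conditions:
        acc = np.array([s.by_condition[c].mean_error_deg for s in summaries])
        prec = np.array([s.by_condition[c].sd_error_deg for s in summaries])
        rt = np.array([s.by_condition[c].mean_reach_time_ms for s in summaries])
        n = acc.size
        out[c] = {
            "accuracy_mean_deg": float(acc.mean()),
            "accuracy_sem_deg": float(np.std(acc, ddof=1) / math.sqrt(n))
            if n > 1
            else 0.0,
            "precision_mean_deg": float(prec.mean()),
            "precision_sd_deg": float(np.std(prec, ddof=1)) if n > 1 else 0.0,
            "reach_time_mean_ms": float(rt.mean()),
            "reach_time_sd_ms": float(np.std(rt, ddof=1)) if n > 1 else 0.0,
            "n": int(n),
        }
    return out


def _measure_vectors(
    summaries: Sequence[ParticipantSummary], condition: str
) -> dict[str, np.ndarray]:
    return {
        "accuracy": np.array(
            [s.by_condition[condition].mean_error_deg for s in summaries]
        ),
        "precision": np.array(
            [s.by_condition[condition].sd_error_deg for s in summaries]
        ),
        "reach_time": np.array(
            [s.by_condition[condition].mean_reach_time_ms for s in summaries]
        ),
    }


def analyze_experiment(
    logs: Sequence[SessionLog],
    design: str = "paired",
    first_n: int | None = None,
    first_n_repeat: int | None = 25,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> StatReport:
    """Run the full battery on a set of session logs.

    ``design="paired"`` (group level): Wilcoxon signed-rank contrasts of
    accuracy, precision and reach time across participants, accuracy vs
    precision Pearson correlation per condition, one-sample t tests on
    per-participant error slopes, with a Shapiro-Wilk diagnostic on each
    measure.  ``design="individual"``: per participant, Mann-Whitney U on
    trial-level errors and (outlier-filtered) reach times plus the
    permutation slope test per condition.  Either way the accuracy contrast
    is repeated on the first ``first_n_repeat`` trials per condition.

    ``first_n`` restricts the *main* battery to the first n trials per
    condition (None = all), so an abbreviated protocol can be analyzed
    as-is.
    """
    if design not in ("paired", "individual"):
        raise ValueError(f"design must be 'paired' or 'individual', got {design!r}")
    if not logs:
        raise InsufficientDataError("no session logs provided")
    experiment = logs[0].protocol.experiment
    conditions = logs[0].protocol.conditions
    for log in logs:
        if log.protocol.experiment != experiment:
            raise ValueError("all logs must come from the same experiment")
    if design == "paired" and len(logs) < 2:
        raise InsufficientDataError("paired design needs >= 2 participants")

    summaries = [summarize_participant(log, first_n=first_n) for log in logs]
    table = summaries_table(summaries)
    group = _group_stats(summaries, conditions)
    c0, c1 = conditions

    repeat = first_n_repeat if first_n_repeat is not None and first_n != first_n_repeat else None
    if repeat is not None:
        summaries25 = [summarize_participant(log, first_n=repeat) for log in logs]
        group25 = _group_stats(summaries25, conditions)
    else:
        summaries25, group25 = None, {}

    normality: dict[str, StatResult] = {}
    tests: dict[str, StatResult] = {}
    slopes: dict[str, dict[str, float]] = {}
    per_participant: dict[str, dict[str, StatResult | PermutationResult]] = {}
    ss = np.random.SeedSequence(seed)

    if design == "paired":
        vec0 = _measure_vectors(summaries, c0)
        vec1 = _measure_vectors(summaries, c1)
        for measure in ("accuracy", "precision", "reach_time"):
            for c, vec in ((c0, vec0), (c1, vec1)):
                try:
                    normality[f"{measure}_{c}"] = shapiro_wilk(vec[measure])
                except (InsufficientDataError, DegenerateStatisticError):
                    pass
            tests[f"{measure}_wilcoxon"] = wilcoxon_paired(
                vec0[measure], vec1[measure]
            )
        for c, vec in ((c0, vec0), (c1, vec1)):
            tests[f"corr_accuracy_precision_{c}"] = pearson_corr(
                vec["accuracy"], vec["precision"]
            )
        for c in conditions:
            per_slopes = np.array(
                [error_slope(log, c, first_n=first_n).slope for log in logs]
            )
            slopes[c] = {
                "mean": float(per_slopes.mean()),
                "sd": float(np.std(per_slopes, ddof=1)),
                "per_participant": [float(s) for s in per_slopes],
            }
            try:
                normality[f"slope_{c}"] = shapiro_wilk(per_slopes)
            except (InsufficientDataError, DegenerateStatisticError):
                pass
            tests[f"slope_t_{c}"] = one_sample_t(per_slopes, mu0=0.0)
        if summaries25 is not None:
            v0 = _measure_vectors(summaries25, c0)["accuracy"]
            v1 = _measure_vectors(summaries25, c1)["accuracy"]
            tests["accuracy_first25_wilcoxon"] = wilcoxon_paired(v0, v1)
    else:
        for log in logs:
            battery: dict[str, StatResult | PermutationResult] = {}
            err0 = [t.error_deg for t in log.condition_trials(c0, first_n=first_n)]
            err1 = [t.error_deg for t in log.condition_trials(c1, first_n=first_n)]
            battery["error_mannwhitney"] = mann_whitney(err0, err1)
            rt0, _ = remove_time_outliers(
                [t.reach_time_ms for t in log.condition_trials(c0, first_n=first_n)]
            )
            rt1, _ = remove_time_outliers(
                [t.reach_time_ms for t in log.condition_trials(c1, first_n=first_n)]
            )
            battery["reach_time_mannwhitney"] = mann_whitney(rt0, rt1)
            if repeat is not None:
                battery["error_first25_mannwhitney"] = mann_whitney(
                    err0[:repeat], err1[:repeat]
                )
            for c in conditions:
                errs = [
                    t.error_deg for t in log.condition_trials(c, first_n=first_n)
                ]
                child = ss.spawn(1)[0]
                perm_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
                battery[f"slope_perm_{c}"] = permutation_slope_test(
                    errs, n_permutations=n_permutations, seed=perm_seed
                )
            for measure, errs in (("error_" + c0, err0), ("error_" + c1, err1)):
                try:
                    normality[f"{log.participant_id}_{measure}"] = shapiro_wilk(errs)
                except (InsufficientDataError, DegenerateStatisticError):
                    pass
            per_participant[log.participant_id] = battery

    n_tests = len(tests) + sum(len(b) for b in per_participant.values())
    return StatReport(
        experiment=experiment,
        design=design,
        conditions=conditions,
        n_participants=len(logs),
        first_n=first_n,
        summaries=table,
        group=group,
        group_first25=group25,
        normality=normality,
        tests=tests,
        slopes=slopes,
        per_participant=per_participant,
        n_tests=n_tests,
        seed=seed,
    )
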
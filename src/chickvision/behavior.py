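"""Trial-level behavioral scoring and the full battery of group analyses.

Trials arrive as a table (one row per trial) with zone-occupancy seconds
for the imprinted-object wall and the unfamiliar-object wall.  The object
preference score is 100 * t_imprinted / (t_imprinted + t_unfamiliar); a
trial is correct when the score strictly exceeds 50%, an exact 50% scores
incorrect, and a trial with zero occupancy of both zones is undefined and
excluded (exclusions are counted, never silent).

The analyses mirror the standard two-alternative forced-choice battery:
per-subject one-tailed exact binomial tests, group mean/SEM, mixed-effects
intercept tests (via :mod:`chickvision.stats`), a 27-cell viewpoint
performance map, viewpoint-magnitude and foreground-pixel correlations,
the pairwise inter-subject correlation matrix with hierarchical-cluster
leaf ordering, day-by-day stability (one-way ANOVA), a familiar-range
novelty-preference control, and regression of preference on image-metric
difference.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from . import stats
from .stimuli import range_center

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "preference_score",
    "score_trial",
    "add_trial_scores",
    "SubjectSummary",
    "subject_summary",
    "all_subject_summaries",
    "group_performance",
    "rest_period_check",
    "viewpoint_map",
    "elevation_magnitude_correlation",
    "foreground_correlation",
    "SubjectCorrelationResult",
    "subject_correlation_matrix",
    "daily_performance",
    "familiar_range_control",
    "mixed_intercept_tests",
    "regress_preference_on_difference",
]

TRIAL_COLUMNS = [
    "subject_id",
    "day",
    "trial_index",
    "trial_kind",
    "viewpoint_range_id",
    "azimuth_center",
    "elevation",
    "is_familiar_range",
    "time_imprinted_s",
    "time_unfamiliar_s",
]


def read_trials(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a trial-log CSV (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing required columns: {missing}")
    if (df[["time_imprinted_s", "time_unfamiliar_s"]] < 0).any().any():
        raise ValueError("occupancy times must be nonnegative")
    bad_kind = set(df["trial_kind"].unique()) - {"test", "rest"}
    if bad_kind:
        raise ValueError(f"unknown trial kinds: {sorted(bad_kind)}")
    return df


def write_trials(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def preference_score(time_imprinted_s: float, time_unfamiliar_s: float) -> float | None:
    """Percent of zone time spent with the imprinted object; None if undefined."""
    if time_imprinted_s < 0 or time_unfamiliar_s < 0:
        raise ValueError("occupancy times must be nonnegative")
    total = time_imprinted_s + time_unfamiliar_s
    if total == 0:
        return None
    return 100.0 * time_imprinted_s / total


def score_trial(row) -> str:
    """Score one test trial: 'correct' | 'incorrect' | 'undefined'."""
    if row["trial_kind"] != "test":
        raise ValueError("only test trials are scored for preference")
    p = preference_score(row["time_imprinted_s"], row["time_unfamiliar_s"])
    if p is None:
        return "undefined"
    return "correct" if p > 50.0 else "incorrect"


def add_trial_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``preference`` and ``correct`` columns added.

    ``preference`` is NaN and ``correct`` is NA for undefined trials; rest
    trials keep NA scores (they are never preference-scored).
    """
    df = trials.copy()
    total = df["time_imprinted_s"] + df["time_unfamiliar_s"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pref = 100.0 * df["time_imprinted_s"] / total
    pref[total == 0] = np.nan
    is_test = df["trial_kind"] == "test"
    df["preference"] = np.where(is_test, pref, np.nan)
    correct = pd.array(pref > 50.0, dtype="boolean")
    correct[~is_test.to_numpy() | pref.isna().to_numpy()] = pd.NA
    df["correct"] = correct
    return df


def _defined_test(trials: pd.DataFrame, exclude_familiar: bool) -> pd.DataFrame:
    df = add_trial_scores(trials)
    df = df[(df["trial_kind"] == "test") & df["correct"].notna()]
    if exclude_familiar:
        df = df[df["is_familiar_range"] == 0]
    return df


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: object
    n_correct: int
    n_trials: int
    n_undefined: int
    percent_correct: float
    mean_preference_percent: float
    binomial_p: float


def subject_summary(
    trials: pd.DataFrame, subject_id, exclude_familiar: bool = False
) -> SubjectSummary:
    """Per-subject correct-trial counts with a one-tailed exact binomial test."""
    sub = trials[trials["subject_id"] == subject_id]
    scored = add_trial_scores(sub)
    test = scored[scored["trial_kind"] == "test"]
    if exclude_familiar:
        test = test[test["is_familiar_range"] == 0]
    defined = test[test["correct"].notna()]
    if len(defined) == 0:
        raise ValueError(f"subject {subject_id!r} has no defined test trials")
    k = int(defined["correct"].sum())
    n = len(defined)
    return SubjectSummary(
        subject_id=subject_id,
        n_correct=k,
        n_trials=n,
        n_undefined=int(len(test) - n),
        percent_correct=100.0 * k / n,
        mean_preference_percent=float(defined["preference"].mean()),
        binomial_p=stats.binomial_tail_one_sided(k, n, 0.5),
    )


def all_subject_summaries(
    trials: pd.DataFrame, exclude_familiar: bool = False
) -> list[SubjectSummary]:
    return [
        subject_summary(trials, s, exclude_familiar)
        for s in sorted(trials["subject_id"].unique())
    ]


def group_performance(
    trials: pd.DataFrame, exclude_familiar: bool = False
) -> tuple[float, float]:
    """(mean, SEM) of subject-level percent-correct values."""
    summaries = all_subject_summaries(trials, exclude_familiar)
    if len(summaries) < 2:
        raise ValueError("need >= 2 subjects")
    pcts = np.array([s.percent_correct for s in summaries])
    return float(pcts.mean()), float(pcts.std(ddof=1) / np.sqrt(pcts.size))


def rest_period_check(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject proportion of rest periods spent nearer the imprinting
    stimulus, with a one-tailed binomial test against 0.5.

    ``imprinting_ok`` flags subjects whose rest preference is significantly
    above chance (p <= 0.05).
    """
    rest = trials[trials["trial_kind"] == "rest"]
    if len(rest) == 0:
        raise ValueError("no rest trials present")
    rows = []
    for sid, sub in rest.groupby("subject_id"):
        near = (sub["time_imprinted_s"] > sub["time_unfamiliar_s"]).sum()
        n = len(sub)
        p = stats.binomial_tail_one_sided(int(near), n, 0.5)
        rows.append(
            {
                "subject_id": sid,
                "n_rest": n,
                "proportion_near_imprint": near / n,
                "binomial_p": p,
                "imprinting_ok": p <= 0.05,
            }
        )
    return pd.DataFrame(rows)


def viewpoint_map(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean percent correct per viewpoint range (27 rows, pooled subjects).

    Ranges with no defined trials appear with NaN performance rather than
    raising.
    """
    df = _defined_test(trials, exclude_familiar=False)
    rows = []
    for rid in range(1, 28):
        az, el = range_center(rid)
        sub = df[df["viewpoint_range_id"] == rid]
        rows.append(
            {
                "viewpoint_range_id": rid,
                "azimuth_center": az,
                "elevation": el,
                "n_trials": len(sub),
                "percent_correct": (
                    100.0 * sub["correct"].mean() if len(sub) else np.nan
                ),
                "mean_preference": (
                    float(sub["preference"].mean()) if len(sub) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def elevation_magnitude_correlation(trials: pd.DataFrame) -> stats.PearsonResult:
    """Correlation of mean preference with |elevation| in {0,15,30,45,60}."""
    df = _defined_test(trials, exclude_familiar=False)
    df = df.assign(magnitude=df["elevation"].abs())
    means = df.groupby("magnitude")["preference"].mean()
    if len(means) < 3:
        raise ValueError("need trials at >= 3 elevation magnitudes")
    return stats.pearson_r_test(means.index.to_numpy(float), means.to_numpy())


def foreground_correlation(
    trials: pd.DataFrame, range_foreground_counts: dict[int, float]
) -> stats.PearsonResult:
    """Correlation of per-range performance with visible foreground pixels.

    ``range_foreground_counts`` maps range id -> mean foreground pixel
    count over the range's three frames (averaged over objects when both
    are in play).
    """
    vm = viewpoint_map(trials)
    vm = vm[vm["percent_correct"].notna()]
    counts = vm["viewpoint_range_id"].map(range_foreground_counts)
    if counts.isna().any():
        missing = vm.loc[counts.isna(), "viewpoint_range_id"].tolist()
        raise ValueError(f"missing foreground counts for ranges {missing}")
    return stats.pearson_r_test(counts.to_numpy(float), vm["mean_preference"].to_numpy())


@dataclass(frozen=True)
class SubjectCorrelationResult:
    subjects: tuple
    matrix: pd.DataFrame  # n x n Pearson r, unit diagonal, NaN for undefined
    pair_r: np.ndarray  # the defined off-diagonal pair correlations
    mean_r: float
    sem_r: float
    t_test: stats.TTestResult
    cluster_order: tuple  # permutation of subjects (clustered leaves first)
    excluded_subjects: tuple  # constant-profile subjects (undefined pairs)


def subject_correlation_matrix(trials: pd.DataFrame) -> SubjectCorrelationResult:
    """Pairwise inter-subject correlation of per-range preference profiles.

    Each subject's profile is the mean preference per viewpoint range;
    pairs are correlated over the ranges both subjects have defined.
    Subjects with a constant profile have undefined correlations and are
    excluded from the mean and the clustering (reported, not silent).
    Leaf order comes from average-linkage clustering on distance 1 - r.
    """
    df = _defined_test(trials, exclude_familiar=False)
    profiles = df.pivot_table(
        index="viewpoint_range_id",
        columns="subject_id",
        values="preference",
        aggfunc="mean",
    )
    subjects = tuple(profiles.columns)
    n = len(subjects)
    if n < 3:
        raise ValueError("need >= 3 subjects")
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    constant = set()
    for i in range(n):
        col = profiles.iloc[:, i].dropna()
        if col.std(ddof=0) == 0:
            constant.add(subjects[i])
    for i in range(n):
        for j in range(i + 1, n):
            if subjects[i] in constant or subjects[j] in constant:
                continue
            pair = profiles.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) >= 3 and x.std() > 0 and y.std() > 0:
                mat[i, j] = mat[j, i] = stats.pearson_r_test(x, y).r
    iu = np.triu_indices(n, k=1)
    pair_r = mat[iu]
    pair_r = pair_r[~np.isnan(pair_r)]
    if pair_r.size < 2:
        raise ValueError("fewer than 2 defined subject pairs")
    mean_r = float(pair_r.mean())
    sem_r = float(pair_r.std(ddof=1) / np.sqrt(pair_r.size))
    if pair_r.std(ddof=1) == 0.0 and mean_r != 0.0:
        # degenerate: every pair identical (e.g. duplicated profiles)
        t_res = stats.TTestResult(np.inf * np.sign(mean_r), pair_r.size - 1, 0.0)
    else:
        t_res = stats.one_sample_t(pair_r, 0.0)

    included = [s for s in subjects if s not in constant]
    inc_idx = [subjects.index(s) for s in included]
    if len(included) >= 3:
        sub = mat[np.ix_(inc_idx, inc_idx)]
        dist = np.clip(1.0 - sub, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        order = [included[i] for i in leaves_list(Z)]
    else:
        order = list(included)
    order += [s for s in subjects if s in constant]
    return SubjectCorrelationResult(
        subjects=subjects,
        matrix=pd.DataFrame(mat, index=subjects, columns=subjects),
        pair_r=pair_r,
        mean_r=mean_r,
        sem_r=sem_r,
        t_test=t_res,
        cluster_order=tuple(order),
        excluded_subjects=tuple(sorted(constant)),
    )


def daily_performance(trials: pd.DataFrame) -> tuple[pd.DataFrame, stats.AnovaResult]:
    """Day-level group means and a one-way ANOVA across test days.

    The ANOVA unit is the day-level subject mean (one percent-correct value
    per subject per day), so 7 days give between-group df = 6.
    """
    df = _defined_test(trials, exclude_familiar=False)
    per = (
        df.groupby(["day", "subject_id"])["correct"]
        .mean()
        .mul(100.0)
        .rename("percent_correct")
        .reset_index()
    )
    days = sorted(per["day"].unique())
    groups = [per.loc[per["day"] == d, "percent_correct"].to_numpy() for d in days]
    anova = stats.one_way_anova(groups)
    daily = per.groupby("day")["percent_correct"].agg(["mean", "sem", "count"]).reset_index()
    return daily, anova


def familiar_range_control(trials: pd.DataFrame, n_quad: int = 21) -> dict:
    """Novelty-preference control on familiar-range test trials only.

    Fits the random-intercept logistic model on trial correctness and the
    random-intercept linear model on the adjusted preference score
    (preference - 50)/100 in [-0.5, 0.5].  A positive significant intercept
    means subjects preferred the imprinted object even when its test
    animation was identical to the imprinting animation, rejecting a pure
    novelty preference.
    """
    df = add_trial_scores(trials)
    fam = df[
        (df["trial_kind"] == "test")
        & (df["is_familiar_range"] == 1)
        & df["correct"].notna()
    ]
    if len(fam) == 0:
        raise ValueError("no familiar-range test trials present")
    outcomes = fam["correct"].astype(int).to_numpy()
    subjects = fam["subject_id"].to_numpy()
    logistic = stats.fit_random_intercept_logistic(outcomes, subjects, n_quad=n_quad)
    adjusted = (fam["preference"].to_numpy() - 50.0) / 100.0
    linear = stats.fit_random_intercept_linear(adjusted, subjects)
    return {"n_trials": int(len(fam)), "logistic": logistic, "linear": linear}


def mixed_intercept_tests(
    trials: pd.DataFrame, exclude_familiar: bool = False, n_quad: int = 21
) -> dict:
    """Group-level above-chance tests: logistic on correctness, linear on
    adjusted preference, both with a subject random intercept."""
    df = _defined_test(trials, exclude_familiar)
    outcomes = df["correct"].astype(int).to_numpy()
    subjects = df["subject_id"].to_numpy()
    logistic = stats.fit_random_intercept_logistic(outcomes, subjects, n_quad=n_quad)
    adjusted = (df["preference"].to_numpy() - 50.0) / 100.0
    linear = stats.fit_random_intercept_linear(adjusted, subjects)
    return {"n_trials": int(len(df)), "logistic": logistic, "linear": linear}


def regress_preference_on_difference(
    condition_preference: np.ndarray, condition_difference: np.ndarray
) -> stats.OLSResult:
    """OLS of per-condition mean preference on image-metric difference.

    With the full 54-condition design the slope t has 52 residual df.
    """
    x = np.asarray(condition_difference, dtype=float)
    y = np.asarray(condition_preference, dtype=float)
    return stats.ols(x, y)
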
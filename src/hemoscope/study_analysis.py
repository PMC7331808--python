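"""Per-subject metrics, condition summaries and rest-vs-stress comparison.

For every subject the same band-power and PRV operations are applied to the
rest and task concentration traces; per-task summaries report means with
standard errors, cross-task pooling weights each task mean by its subject
count, percent change is computed on condition means, and significance uses
a two-sided paired t-test (each subject is their own control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .concentration_imaging import ConcentrationSeries
from .hemodynamics import (
    BVP_BAND,
    VASO_BAND,
    Waveform,
    band_integrated_power,
    detect_beats,
    extract_bvp,
    extract_vasomotion,
    prv_spectrum,
    prv_summary,
)

__all__ = [
    "SubjectMetrics",
    "TaskSummary",
    "PooledSummary",
    "ComparisonResult",
    "METRIC_NAMES",
    "condition_metrics",
    "subject_metrics",
    "summarize_task",
    "pool_tasks",
    "percent_change",
    "compare_conditions",
]

METRIC_NAMES = (
    "vasomotion_power",
    "bvp_power",
    "prv_lf",
    "prv_hf",
    "prv_lf_normalized",
    "prv_hf_normalized",
    "prv_lf_hf",
)


@dataclass(frozen=True)
class SubjectMetrics:
    """One subject's per-condition metric dictionaries (keys METRIC_NAMES)."""

    subject_id: str
    rest: dict
    task: dict


@dataclass(frozen=True)
class TaskSummary:
    """Per-task, per-condition means and standard errors (SE = SD/sqrt(n))."""

    task: str
    n: int
    means: dict  # {condition: {metric: value}}
    standard_errors: dict

    def mean(self, condition: str, metric: str) -> float:
        return self.means[condition][metric]


@dataclass(frozen=True)
class PooledSummary:
    """Subject-count-weighted cross-task means per metric and condition."""

    total_n: int
    means: dict


@dataclass(frozen=True)
class ComparisonResult:
    """Rest-vs-task comparison of one metric."""

    metric: str
    percent_change: float
    percent_change_per_subject_mean: float
    percent_change_per_subject_sd: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def condition_metrics(series: ConcentrationSeries) -> dict:
    """All per-condition metrics from one total-blood-concentration trace."""
    ctb = Waveform(series.c_tb, series.fs)
    vaso = extract_vasomotion(ctb)
    bvp = extract_bvp(ctb)
    out = {
        "vasomotion_power": band_integrated_power(vaso, VASO_BAND).value,
        "bvp_power": band_integrated_power(bvp, BVP_BAND).value,
    }
    try:
        ibis = detect_beats(ctb)
        summary = prv_summary(prv_spectrum(ibis))
        out.update(
            prv_lf=summary.lf,
            prv_hf=summary.hf,
            prv_lf_normalized=summary.lf_normalized,
            prv_hf_normalized=summary.hf_normalized,
            prv_lf_hf=summary.lf_hf,
        )
    except ValueError:
        out.update({k: float("nan") for k in METRIC_NAMES[2:]})
    return out


def subject_metrics(
    rest: ConcentrationSeries, task: ConcentrationSeries, subject_id: str = "s0"
) -> SubjectMetrics:
    """Apply the identical metric pipeline to both conditions of a subject."""
    return SubjectMetrics(
        subject_id, condition_metrics(rest), condition_metrics(task)
    )


def summarize_task(metrics: list[SubjectMetrics], task_name: str) -> TaskSummary:
    """Per-metric mean and standard error for each condition.

    SE = sample SD / sqrt(n) (ddof=1); for n = 1 the SE is reported as NaN.
    """
    if not metrics:
        raise ValueError("cannot summarize an empty metric list")
    n = len(metrics)
    names = sorted(set().union(*(set(m.rest) | set(m.task) for m in metrics)))
    means: dict = {}
    ses: dict = {}
    for condition in ("rest", "task"):
        means[condition] = {}
        ses[condition] = {}
        for name in names:
            vals = np.array([getattr(m, condition).get(name, np.nan) for m in metrics])
            means[condition][name] = float(np.nanmean(vals))
            if n > 1:
                ses[condition][name] = float(np.nanstd(vals, ddof=1) / np.sqrt(n))
            else:
                ses[condition][name] = float("nan")
    return TaskSummary(task_name, n, means, ses)


def pool_tasks(summaries: list[TaskSummary]) -> PooledSummary:
    """Subject-count-weighted pooled means: sum(n_i * mean_i) / sum(n_i)."""
    total = sum(s.n for s in summaries)
    if total <= 0:
        raise ValueError("pooling requires a positive total subject count")
    means: dict = {}
    for condition in ("rest", "task"):
        means[condition] = {}
        metrics = set().union(*(s.means[condition].keys() for s in summaries))
        for name in metrics:
            means[condition][name] = (
                sum(s.n * s.means[condition][name] for s in summaries) / total
            )
    return PooledSummary(total, means)


def percent_change(rest_mean: float, task_mean: float) -> float:
    """Percent decrease from rest to task: 100 * (rest - task) / rest."""
    if not rest_mean > 0:
        raise ValueError("percent change requires a positive rest mean")
    return 100.0 * (rest_mean - task_mean) / rest_mean


def compare_conditions(
    rest_values: np.ndarray,
    task_values: np.ndarray,
    alpha: float = 0.05,
    metric: str = "",
    paired: bool = True,
) -> ComparisonResult:
    """Two-sided (paired by default) t-test plus percent-change summaries.

    The headline percent change is computed on the condition means; the
    mean and SD of the per-subject percent changes are reported alongside
    (their dispersion is the natural error measure of the effect size).
    """
    rest = np.asarray(rest_values, dtype=float)
    task = np.asarray(task_values, dtype=float)
    if paired and rest.shape != task.shape:
        raise ValueError("paired comparison requires equal-length samples")
    if rest.size < 2 or task.size < 2:
        raise ValueError("at least two subjects are required")
    keep = np.isfinite(rest) & np.isfinite(task) if paired else slice(None)
    rest, task = rest[keep], task[keep]
    if paired and np.allclose(rest, task):
        t_stat, p_val = 0.0, 1.0
    elif paired:
        t_stat, p_val = stats.ttest_rel(rest, task)
    else:
        t_stat, p_val = stats.ttest_ind(rest, task)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_subject = 100.0 * (rest - task) / rest
    per_subject = per_subject[np.isfinite(per_subject)]
    return ComparisonResult(
        metric=metric,
        percent_change=percent_change(float(rest.mean()), float(task.mean())),
        percent_change_per_subject_mean=float(per_subject.mean()),
        percent_change_per_subject_sd=float(per_subject.std(ddof=1)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        significant=bool(p_val < alpha),
        alpha=alpha,
    )


def metrics_table(all_metrics: dict[str, list[SubjectMetrics]]) -> pd.DataFrame:
    """Long-format per-subject table across tasks (one row per condition)."""
    rows = []
    for task_name, subjects in all_metrics.items():
        for m in subjects:
            for condition in ("rest", "task"):
                row = {"task": task_name, "subject": m.subject_id,
                       "condition": condition}
                row.update(getattr(m, condition))
                rows.append(row)
    return pd.DataFrame(rows)
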
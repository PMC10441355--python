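"""Clock scoring and treatment-effect quantification.

Metrics follow the conventions of the epigenetic-clock literature: the age
correlation R is the Pearson correlation between DNAm age and chronological
age; accuracy is the median absolute error in years; epigenetic age
acceleration is DNAm age minus chronological age (a residual-based variant
is available and labelled as such).

The rejuvenation percentage of a treatment is the fraction of the
old-control mean epigenetic age removed by it:

    100 * (mean_old_control - mean_old_treated) / mean_old_control

so a value above 50% means the treatment more than halved the epigenetic
age.  A gap-closure variant relative to the young arm,
100 * (old - treated) / (old - young), is reported alongside as a labelled
secondary statistic.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_methylation import ValidationError

__all__ = [
    "GroupComparison",
    "RejuvenationReport",
    "pearson_r",
    "median_abs_error",
    "age_acceleration",
    "group_stats",
    "rejuvenation_percent",
    "summarize_rejuvenation",
]


@dataclasses.dataclass
class GroupComparison:
    """Per-group summaries plus omnibus and two-group test p-values."""

    groups: pd.DataFrame  # group, n, mean, se
    anova_p: float
    t_p: float  # old_control vs old_treated, young excluded; NaN if absent
    t_stat: float
    kruskal_p: float


@dataclasses.dataclass
class RejuvenationReport:
    per_clock: pd.DataFrame  # tissue, clock, group means, rejuvenation_pct, ...
    per_tissue: pd.DataFrame  # tissue, mean over clocks (both averaging orders)
    grand_average: float  # unweighted mean over tissues of per-clock averages
    grand_average_ratio_of_means: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def median_abs_error(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Median of |pred - truth|, in the units of the inputs (years here)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 1:
        raise ValidationError("median_abs_error needs equal-length vectors")
    return float(np.median(np.abs(pred - truth)))


def age_acceleration(predictions: pd.DataFrame,
                     mode: str = "difference") -> pd.Series:
    """Epigenetic age acceleration per sample.

    ``difference`` (default): dnam_age - chronological_age.
    ``residual``: residuals of dnam_age regressed on chronological age; a
    distinct quantity, returned under the name ``age_acceleration_residual``.
    """
    dnam = predictions["dnam_age"].to_numpy(dtype=float)
    age = predictions["chronological_age"].to_numpy(dtype=float)
    if mode == "difference":
        return pd.Series(dnam - age, index=predictions.index,
                         name="age_acceleration")
    if mode == "residual":
        slope, intercept = np.polyfit(age, dnam, 1)
        return pd.Series(dnam - (intercept + slope * age),
                         index=predictions.index,
                         name="age_acceleration_residual")
    raise ValidationError(f"unknown age-acceleration mode {mode!r}")


def group_stats(values: Sequence[float], groups: Sequence[str],
                welch: bool = False) -> GroupComparison:
    """One-way ANOVA, old-control vs old-treated t-test, and Kruskal-Wallis.

    The t-test is the classical equal-variance Student form by default
    (``welch=True`` switches to Welch); it compares only the old_control
    and old_treated groups, excluding young controls.  Kruskal-Wallis is
    two-sided across all groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    by_group = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in by_group):
        raise ValidationError("each group needs n >= 2")

    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [len(v) for v in by_group],
            "mean": [float(np.mean(v)) for v in by_group],
            "se": [float(np.std(v, ddof=1) / np.sqrt(len(v)))
                   for v in by_group],
        }
    )
    anova_p = float(stats.f_oneway(*by_group).pvalue)
    if all(np.ptp(v) == 0 for v in by_group) and len({v[0] for v in by_group}) == 1:
        kruskal_p, kruskal_h = 1.0, 0.0  # identical samples carry no evidence
    else:
        kr = stats.kruskal(*by_group)
        kruskal_p, kruskal_h = float(kr.pvalue), float(kr.statistic)

    t_stat = t_p = float("nan")
    if "old_control" in labels and "old_treated" in labels:
        a = values[groups == "old_control"]
        b = values[groups == "old_treated"]
        if np.ptp(np.concatenate([a, b])) == 0:
            t_stat, t_p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            t_stat, t_p = float(res.statistic), float(res.pvalue)
    return GroupComparison(summary, anova_p, t_p, t_stat, kruskal_p)


def rejuvenation_percent(mean_old_control: float,
                         mean_old_treated: float) -> float:
    """Percent of old-control mean epigenetic age removed by treatment."""
    if not mean_old_control > 0:
        raise ValidationError("old-control mean age must be positive")
    return 100.0 * (mean_old_control - mean_old_treated) / mean_old_control


def gap_closure_percent(mean_young: float, mean_old_control: float,
                        mean_old_treated: float) -> float:
    """Secondary statistic: percent of the old-young gap closed."""
    gap = mean_old_control - mean_young
    if not gap > 0:
        raise ValidationError("old-control mean must exceed young mean")
    return 100.0 * (mean_old_control - mean_old_treated) / gap


def summarize_rejuvenation(
    predictions: pd.DataFrame,
    clock_col: str = "clock",
) -> RejuvenationReport:
    """Per-clock, per-tissue and grand-average rejuvenation percentages.

    ``predictions`` holds one row per sample per clock with columns
    ``tissue``, ``clock``, ``group`` and ``dnam_age``; every tissue must
    contain all three treatment groups.  Group means are arithmetic means
    of per-sample DNAm ages.  Per-tissue values average the per-clock
    ratios; the ratio of per-tissue mean ages (the other averaging order)
    is reported alongside.  The grand average is the unweighted mean of
    the per-tissue averages.
    """
    required = {"tissue", clock_col, "group", "dnam_age"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValidationError(f"prediction table lacks columns {sorted(missing)}")
    rows = []
    for (tissue, clock), sub in predictions.groupby(["tissue", clock_col],
                                                    sort=True):
        means: Mapping[str, float] = sub.groupby("group")["dnam_age"].mean()
        needed = {"young_control", "old_control", "old_treated"}
        if not needed <= set(means.index):
            raise ValidationError(
                f"tissue {tissue!r} clock {clock!r} lacks groups "
                f"{sorted(needed - set(means.index))}"
            )
        young = float(means["young_control"])
        old = float(means["old_control"])
        treated = float(means["old_treated"])
        rows.append(
            {
                "tissue": tissue,
                "clock": clock,
                "mean_age_young": young,
                "mean_age_old_control": old,
                "mean_age_old_treated": treated,
                "rejuvenation_pct": rejuvenation_percent(old, treated),
                "rejuvenation_pct_gap_closure": gap_closure_percent(
                    young, old, treated
                ),
            }
        )
    per_clock = pd.DataFrame(rows)
    per_tissue_rows = []
    for tissue, sub in per_clock.groupby("tissue", sort=True):
        ratio_of_means = rejuvenation_percent(
            sub["mean_age_old_control"].mean(),
            sub["mean_age_old_treated"].mean(),
        )
        per_tissue_rows.append(
            {
                "tissue": tissue,
                "rejuvenation_pct": float(sub["rejuvenation_pct"].mean()),
                "rejuvenation_pct_ratio_of_means": ratio_of_means,
            }
        )
    per_tissue = pd.DataFrame(per_tissue_rows)
    return RejuvenationReport(
        per_clock=per_clock,
        per_tissue=per_tissue,
        grand_average=float(per_tissue["rejuvenation_pct"].mean()),
        grand_average_ratio_of_means=float(
            per_tissue["rejuvenation_pct_ratio_of_means"].mean()
        ),
    )
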
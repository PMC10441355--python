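"""IgG Fc N-glycan aging analysis.

Raw chromatogram areas are normalized to the total within each sample and
IgG subclass (IgG2a/IgG2b/IgG2c), giving relative glycoform abundances on
the simplex.  Abundances are transformed to standard normal scores by
rank-based inverse-normal transformation, making effect estimates
comparable across glycoforms.  Two analyses follow:

* cross-sectional: each glycoform's transformed abundance regressed on
  chronological age with sex as a covariate, BH-adjusted across the panel;
* longitudinal: a linear mixed-effects model with fixed time and
  time x treatment effects and a per-subject random intercept (REML),
  testing whether treatment bends the aging trajectory.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_methylation import ValidationError
from .ewas import bh_adjust

__all__ = [
    "normalize_to_subclass_total",
    "rank_inverse_normal",
    "age_association_glm",
    "treatment_mixed_model",
    "baseline_normalized_change",
]

GLYCO_KEYS = ["sample_id", "subject_id", "arm", "timepoint", "subclass",
              "glycoform"]


def normalize_to_subclass_total(areas: pd.DataFrame) -> pd.DataFrame:
    """Divide each raw area by its sample x subclass total.

    ``areas`` is long-format with an ``area`` column; the result replaces
    it with ``relative_abundance`` summing to 1 within each sample and
    subclass.
    """
    if "area" not in areas.columns:
        raise ValidationError("expected long-format table with an 'area' column")
    if (areas["area"] < 0).any():
        raise ValidationError("areas must be non-negative")
    out = areas.copy()
    totals = out.groupby(["sample_id", "subclass"])["area"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = out.loc[zero, ["sample_id", "subclass"]].drop_duplicates()
        raise ValidationError(
            f"all-zero subclass totals for {bad.values.tolist()[:5]}"
        )
    out["relative_abundance"] = out["area"] / totals
    return out.drop(columns=["area"])


def rank_inverse_normal(x) -> np.ndarray:
    """Map values to normal scores: Phi^-1((rank - 0.5) / n), average ties."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("rank transform needs at least 2 values")
    if np.ptp(x) == 0:
        raise ValidationError("rank transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def _transform_column(values: pd.Series, how: str) -> np.ndarray:
    if how == "rint":
        return rank_inverse_normal(values.to_numpy())
    if how == "none":
        return values.to_numpy(dtype=float)
    raise ValidationError(f"unknown transform {how!r}")


def age_association_glm(
    table: pd.DataFrame,
    ages: pd.Series,
    sex: pd.Series,
    transform: str = "rint",
) -> pd.DataFrame:
    """Per-glycoform regression of transformed abundance on age and sex.

    ``table`` holds one timepoint in long format; ``ages`` (years) and
    ``sex`` are indexed by sample_id.  Returns subclass, glycoform, the age
    coefficient, two-sided p and BH q across the glycoform panel.
    """
    rows = []
    for (subclass, glycoform), sub in table.groupby(["subclass", "glycoform"],
                                                    sort=True):
        sub = sub.drop_duplicates("sample_id")
        if len(sub) < 4:
            raise ValidationError(
                f"{subclass}/{glycoform}: need n >= 4 samples"
            )
        y = _transform_column(sub["relative_abundance"], transform)
        age = ages.loc[sub["sample_id"]].to_numpy(dtype=float)
        sex_codes = pd.Categorical(sex.loc[sub["sample_id"]]).codes.astype(float)
        X = pd.DataFrame({"age": age})
        if np.ptp(sex_codes) > 0:
            X["sex"] = sex_codes
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValidationError(
                f"{subclass}/{glycoform}: collinear age/sex coding"
            )
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "subclass": subclass,
                "glycoform": glycoform,
                "age_coef": float(fit.params["age"]),
                "p": float(fit.pvalues["age"]),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def treatment_mixed_model(table: pd.DataFrame,
                          transform: str = "rint") -> pd.DataFrame:
    """Per-glycoform mixed model: time + time x treatment, random intercept.

    Fixed effects: ``time`` (0 baseline, 1 follow-up) and its interaction
    with the treated arm; each subject contributes a random intercept.
    Fitting is by REML; fixed-effect p-values use the normal approximation
    to the Wald statistic.  Non-convergence is reported per glycoform
    without aborting the rest of the panel.
    """
    needed = set(GLYCO_KEYS + ["relative_abundance"])
    if not needed <= set(table.columns):
        raise ValidationError(f"table lacks columns {sorted(needed - set(table.columns))}")
    rows = []
    for (subclass, glycoform), sub in table.groupby(["subclass", "glycoform"],
                                                    sort=True):
        sub = sub.copy()
        counts = sub.groupby(["arm", "subject_id"])["timepoint"].nunique()
        ok_arms = counts[counts == 2].groupby("arm").size()
        if not {"treated", "control"} <= set(ok_arms.index) or (ok_arms < 2).any():
            raise ValidationError(
                f"{subclass}/{glycoform}: need >= 2 subjects per arm with "
                "both timepoints"
            )
        y = _transform_column(sub["relative_abundance"], transform)
        time = (sub["timepoint"] == "followup").to_numpy(dtype=float)
        treated = (sub["arm"] == "treated").to_numpy(dtype=float)
        X = pd.DataFrame(
            {"const": 1.0, "time": time, "time_treated": time * treated}
        )
        row = {"subclass": subclass, "glycoform": glycoform}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                # zero-variance boundary fits warn but remain usable
                warnings.simplefilter("ignore", UserWarning)
                fit = MixedLM(y, X, groups=sub["subject_id"].to_numpy()).fit(
                    reml=True
                )
            row.update(
                {
                    "time_effect": float(fit.params["time"]),
                    "time_p": float(fit.pvalues["time"]),
                    "interaction_effect": float(fit.params["time_treated"]),
                    "interaction_p": float(fit.pvalues["time_treated"]),
                    "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
                    "converged": bool(fit.converged),
                }
            )
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            row.update(
                {
                    "time_effect": np.nan,
                    "time_p": np.nan,
                    "interaction_effect": np.nan,
                    "interaction_p": np.nan,
                    "random_intercept_var": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["interaction_p"].notna()
    out["interaction_q"] = np.nan
    if valid.any():
        out.loc[valid, "interaction_q"] = bh_adjust(
            out.loc[valid, "interaction_p"]
        )
    return out


def baseline_normalized_change(table: pd.DataFrame) -> pd.DataFrame:
    """Follow-up minus baseline abundance per subject (export convenience)."""
    wide = table.pivot_table(
        index=["subject_id", "arm", "subclass", "glycoform"],
        columns="timepoint",
        values="relative_abundance",
    ).reset_index()
    if not {"baseline", "followup"} <= set(wide.columns):
        raise ValidationError("need both baseline and followup timepoints")
    wide["change_from_baseline"] = wide["followup"] - wide["baseline"]
    return wide[["subject_id", "arm", "subclass", "glycoform",
                 "change_from_baseline"]]
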
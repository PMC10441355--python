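"""Per-CpG EWAS of age and treatment with unwanted-variation correction.

Each probe's beta values are regressed on a cell-means design
(``~ 0 + condition + plate + column [+ RUV factors]``).  Latent technical
factors are estimated from empirical negative-control probes (the probes
least associated with age and condition) by SVD of the row-centred control
submatrix.  Per-probe residual variances are shrunk toward a common prior
by empirical-Bayes moment matching on log s^2 (Smyth-style), yielding
moderated t-statistics with d0 + d degrees of freedom.  Contrasts of the
condition means — e.g. treatment = old_treated - old_control,
age = old_control - young_control — are tested two-sided with
Benjamini-Hochberg adjustment within each contrast.

The reversal summary asks, among probes significant for the age contrast,
how often the treatment estimate has the opposite sign — split by
age-gain versus age-loss probes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_methylation import BetaMatrix, ValidationError

__all__ = [
    "RuvFactors",
    "EwasFit",
    "select_control_probes",
    "estimate_ruv_factors",
    "build_design",
    "fit_probe_models",
    "ebayes_moderate",
    "apply_contrast",
    "bh_adjust",
    "reversal_summary",
]


@dataclasses.dataclass
class RuvFactors:
    """Sample loadings of the top-k control-probe singular vectors."""

    factors: np.ndarray  # samples x k, orthonormal columns
    control_probes: list[str]

    @property
    def k(self) -> int:
        return self.factors.shape[1]


@dataclasses.dataclass
class EwasFit:
    probe_ids: np.ndarray
    design: pd.DataFrame
    coefficients: np.ndarray  # probes x design columns
    s2: np.ndarray  # residual variance per probe
    df_residual: int
    xtx_inv: np.ndarray
    d0: float | None = None  # prior df (None until moderated; inf allowed)
    s0_2: float | None = None  # prior variance

    @property
    def columns(self) -> list[str]:
        return list(self.design.columns)


def select_control_probes(m: BetaMatrix, ann: pd.DataFrame,
                          n_controls: int = 500) -> list[str]:
    """Empirical negative controls: probes least associated with age/condition.

    Probes are ranked by |Pearson r| with age and by the one-way ANOVA F
    statistic across treatment groups (zero if fewer than two groups are
    present); the ``n_controls`` probes with the smallest rank-sum are
    returned.  Ties resolve by probe id, so the set is deterministic.
    """
    if not 0 < n_controls < m.n_probes:
        raise ValidationError("need 0 < n_controls < total probes")
    ann = ann.set_index("sample_id").loc[list(m.sample_ids)].reset_index()
    B = m.values
    age = ann["age"].to_numpy(dtype=float)
    if np.ptp(age) > 0:
        Bc = B - B.mean(axis=1, keepdims=True)
        ac = age - age.mean()
        denom = np.sqrt((Bc**2).sum(axis=1) * (ac**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r_age = np.where(denom > 0, (Bc @ ac) / denom, 0.0)
    else:
        r_age = np.zeros(m.n_probes)

    groups = ann["group"].to_numpy(dtype=object)
    labels = [g for g in pd.unique(groups) if g != "none"]
    if len(labels) >= 2:
        grand = B.mean(axis=1)
        n = B.shape[1]
        ss_between = np.zeros(m.n_probes)
        ss_within = np.zeros(m.n_probes)
        for g in labels:
            sub = B[:, groups == g]
            ng = sub.shape[1]
            gm = sub.mean(axis=1)
            ss_between += ng * (gm - grand) ** 2
            ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
        df_b = len(labels) - 1
        df_w = n - len(labels)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_cond = np.where(ss_within > 0,
                              (ss_between / df_b) / (ss_within / df_w), 0.0)
    else:
        f_cond = np.zeros(m.n_probes)

    order = pd.DataFrame(
        {"probe_id": [str(p) for p in m.probe_ids],
         "abs_r_age": np.abs(r_age), "f_cond": f_cond}
    )
    order["rank_sum"] = (
        order["abs_r_age"].rank(method="average")
        + order["f_cond"].rank(method="average")
    )
    order = order.sort_values(["rank_sum", "probe_id"], kind="mergesort")
    return order["probe_id"].head(n_controls).tolist()


def estimate_ruv_factors(m: BetaMatrix, control_probes: Sequence[str],
                         k: int = 2) -> RuvFactors:
    """SVD factors of the row-centred control-probe submatrix."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    controls = list(control_probes)
    if k == 0:
        return RuvFactors(np.empty((m.n_samples, 0)), controls)
    sub = m.select_probes(controls).values
    centred = sub - sub.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(centred)
    if k > rank:
        raise ValidationError(f"k={k} exceeds control-submatrix rank {rank}")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return RuvFactors(vt[:k].T.copy(), controls)


def build_design(
    ann: pd.DataFrame,
    ruv: RuvFactors | None = None,
    condition_col: str = "group",
    plate_col: str = "batch_plate",
    column_col: str = "batch_column",
) -> pd.DataFrame:
    """Cell-means design: condition indicators plus batch dummies and factors.

    Condition gets one indicator per level (no global intercept); plate and
    array-column dummies drop their first level to avoid aliasing.  Raises
    if the result is rank deficient, naming the aliased columns.
    """
    cond = pd.get_dummies(ann[condition_col], prefix="condition",
                          dtype=float)
    parts = [cond]
    for col, prefix in ((plate_col, "plate"), (column_col, "col")):
        if col in ann.columns and ann[col].nunique() > 1:
            parts.append(pd.get_dummies(ann[col], prefix=prefix,
                                        drop_first=True, dtype=float))
    design = pd.concat(parts, axis=1)
    if ruv is not None and ruv.k > 0:
        for j in range(ruv.k):
            design[f"ruv{j + 1}"] = ruv.factors[:, j]
    design.index = ann["sample_id"].to_numpy()
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(design)
        raise ValidationError(f"design is rank deficient; aliased: {aliased}")
    return design


def _aliased_columns(design: pd.DataFrame) -> list[str]:
    kept: list[str] = []
    aliased: list[str] = []
    X = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        trial = X[:, [design.columns.get_loc(c) for c in kept] + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(name)
        else:
            aliased.append(name)
    return aliased


def fit_probe_models(m: BetaMatrix, design: pd.DataFrame) -> EwasFit:
    """Ordinary least squares of every probe's betas on the shared design."""
    if np.isnan(m.values).any():
        raise ValidationError("impute missing values before the EWAS fit")
    if list(design.index) != [str(s) for s in m.sample_ids]:
        raise ValidationError("design row order must match the sample order")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError(
            f"design is rank deficient; aliased: {_aliased_columns(design)}"
        )
    df = n - rank
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = m.values  # probes x samples
    coef = (xtx_inv @ (X.T @ B.T)).T  # probes x p
    resid = B - coef @ X.T
    s2 = (resid**2).sum(axis=1) / df
    return EwasFit(
        probe_ids=np.array([str(q) for q in m.probe_ids], dtype=object),
        design=design,
        coefficients=coef,
        s2=s2,
        df_residual=df,
        xtx_inv=xtx_inv,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def ebayes_moderate(fit: EwasFit) -> EwasFit:
    """Estimate (d0, s0^2) by moment matching on log s^2 and shrink variances.

    With z = log s^2, E[z] = log s0^2 + psi(d/2) - log(d/2) + log(d0/2)
    - psi(d0/2) and Var[z] = psi'(d/2) + psi'(d0/2) under the scaled-F
    model.  Excess variance of z beyond psi'(d/2) identifies d0 via the
    trigamma inverse; no excess means no evidence of heterogeneity and
    d0 = infinity (complete pooling).  Probes with s^2 = 0 are offset by a
    tiny fraction of the smallest positive variance before taking logs.
    """
    s2 = fit.s2.copy()
    d = float(fit.df_residual)
    if len(s2) < 2:
        raise ValidationError("moderation needs at least 2 probes")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValidationError("all residual variances are zero")
    s2 = np.where(s2 > 0, s2, positive.min() * 1e-8)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(
            e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        ))
    else:
        # no dispersion beyond sampling noise: complete pooling
        d0 = np.inf
        s0_2 = float(s2.mean())
    fit.d0 = d0
    fit.s0_2 = s0_2
    return fit


def moderated_s2(fit: EwasFit) -> np.ndarray:
    """Posterior (shrunken) residual variances (d0*s0^2 + d*s^2)/(d0 + d)."""
    if fit.d0 is None:
        raise ValidationError("call ebayes_moderate before using moderated_s2")
    d = float(fit.df_residual)
    if np.isinf(fit.d0):
        return np.full_like(fit.s2, fit.s0_2)
    return (fit.d0 * fit.s0_2 + d * fit.s2) / (fit.d0 + d)


def apply_contrast(
    fit: EwasFit,
    contrast: Mapping[str, float],
    name: str = "contrast",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated t-test of a linear combination of design coefficients.

    Returns a per-probe table with the estimate, moderated t, two-sided p,
    BH-adjusted q (within this contrast) and the q < threshold flag.
    """
    unknown = sorted(set(contrast) - set(fit.columns))
    if unknown:
        raise ValidationError(f"contrast references unknown columns {unknown}")
    c = np.zeros(len(fit.columns))
    for col, w in contrast.items():
        c[fit.columns.index(col)] = w
    estimate = fit.coefficients @ c
    var_unscaled = float(c @ fit.xtx_inv @ c)
    if fit.d0 is None:
        s2_use = fit.s2
        df_total = float(fit.df_residual)
    else:
        s2_use = moderated_s2(fit)
        # total df capped at the pooled residual df across probes
        df_total = min(fit.d0 + fit.df_residual,
                       len(fit.s2) * fit.df_residual)
    se = np.sqrt(var_unscaled * s2_use)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, estimate / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "probe_id": fit.probe_ids,
            "contrast": name,
            "estimate": estimate,
            "t_moderated": t,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def reversal_summary(age_results: pd.DataFrame,
                     treatment_results: pd.DataFrame) -> dict:
    """Sign-reversal statistics among age-significant probes.

    For probes significant in the age contrast, counts how many have a
    treatment estimate of opposite sign, overall and split by direction of
    the age effect (gain vs loss of methylation with age).
    """
    if set(age_results["probe_id"]) != set(treatment_results["probe_id"]):
        raise ValidationError("contrasts cover different probe universes")
    merged = age_results.merge(
        treatment_results, on="probe_id", suffixes=("_age", "_treatment")
    )
    sig = merged[merged["significant_age"]]
    out = {
        "n_age_significant": int(len(sig)),
        "n_reversed": 0,
        "proportion_reversed": float("nan"),
        "gain": {"n": 0, "n_reversed": 0, "proportion_reversed": float("nan")},
        "loss": {"n": 0, "n_reversed": 0, "proportion_reversed": float("nan")},
    }
    if sig.empty:
        return out
    reversed_mask = (
        np.sign(sig["estimate_treatment"]) == -np.sign(sig["estimate_age"])
    ) & (sig["estimate_age"] != 0)
    out["n_reversed"] = int(reversed_mask.sum())
    out["proportion_reversed"] = float(reversed_mask.mean())
    for label, mask in (
        ("gain", sig["estimate_age"] > 0),
        ("loss", sig["estimate_age"] < 0),
    ):
        n = int(mask.sum())
        n_rev = int((reversed_mask & mask).sum())
        out[label] = {
            "n": n,
            "n_reversed": n_rev,
            "proportion_reversed": n_rev / n if n else float("nan"),
        }
    return out
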
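"""Penalized-regression epigenetic clocks.

A clock is a sparse linear model predicting (transformed) age from CpG
beta values, fitted with the elastic net at mixing parameter 0.5 — the
midpoint between ridge and lasso — with the penalty strength chosen by an
internal 10-fold cross-validation minimizing mean squared error.  Two age
transforms are supported:

* ``identity`` — the response is chronological age in years;
* ``relative`` — the response is age divided by the species' maximum
  lifespan (rat 3.8 y, human 122.5 y), mapping both species onto [0, 1]
  so a single clock can serve species with very different lifespans.

Cross-validation (leave-one-out or k-fold) refits the entire procedure,
including the internal penalty selection, on every training subset, so a
held-out sample never influences its own prediction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .io_methylation import BetaMatrix, ValidationError

__all__ = [
    "DEFAULT_MAX_LIFESPAN",
    "AgeTransform",
    "ClockModel",
    "CVReport",
    "relative_age",
    "fit_clock",
    "predict_age",
    "cross_validate",
    "save_clock",
    "load_clock",
]

DEFAULT_MAX_LIFESPAN: Mapping[str, float] = {"rat": 3.8, "human": 122.5}

ALPHA = 0.5  # elastic-net mixing, fixed by design and not tuned

# penalty path resolution for the internal 10-fold selection
N_LAMBDAS = 40
LAMBDA_MIN_RATIO = 1e-2


def relative_age(age: float, species: str,
                 max_lifespan: Mapping[str, float] | None = None) -> float:
    """Age divided by the species' maximum lifespan.

    Values above 1 (ages beyond the nominal maximum) are permitted with a
    warning rather than an error.
    """
    lifespans = DEFAULT_MAX_LIFESPAN if max_lifespan is None else max_lifespan
    if species not in lifespans:
        raise ValidationError(f"no maximum lifespan configured for {species!r}")
    if age < 0:
        raise ValidationError("age must be >= 0")
    ratio = age / lifespans[species]
    if ratio > 1:
        warnings.warn(
            f"age {age} exceeds the nominal maximum lifespan of {species}",
            stacklevel=2,
        )
    return ratio


@dataclasses.dataclass
class AgeTransform:
    """Maps chronological age to the regression response and back."""

    kind: str = "identity"
    max_lifespan_by_species: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MAX_LIFESPAN)
    )

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "relative"):
            raise ValidationError(f"unknown transform kind {self.kind!r}")

    def forward(self, ages: np.ndarray, species: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.kind == "identity":
            return ages
        return ages / self._lifespans(species)

    def inverse(self, scores: np.ndarray, species: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.kind == "identity":
            return scores
        return scores * self._lifespans(species)

    def _lifespans(self, species: np.ndarray) -> np.ndarray:
        unknown = sorted(set(np.asarray(species, dtype=object))
                         - set(self.max_lifespan_by_species))
        if unknown:
            raise ValidationError(f"no maximum lifespan for species {unknown}")
        return np.array(
            [self.max_lifespan_by_species[s] for s in species], dtype=float
        )


@dataclasses.dataclass
class ClockModel:
    """Sparse probe weights + intercept + age transform."""

    probe_weights: dict[str, float]
    intercept: float
    transform: AgeTransform
    training_meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return sum(1 for w in self.probe_weights.values() if w != 0.0)


@dataclasses.dataclass
class CVReport:
    scheme: str
    predictions: pd.DataFrame  # sample_id, species, tissue, age, dnam_age, fold
    pearson_r: float
    median_abs_error: float
    seed: int


def _training_arrays(
    m: BetaMatrix,
    ann: pd.DataFrame,
    tissue_filter: Iterable[str] | None,
) -> tuple[np.ndarray, pd.DataFrame]:
    ann = ann.set_index("sample_id").loc[list(m.sample_ids)].reset_index()
    if tissue_filter is not None:
        keep = ann["tissue"].isin(set(tissue_filter)).to_numpy()
        if not keep.any():
            raise ValidationError("tissue filter excludes every sample")
        ann = ann.loc[keep].reset_index(drop=True)
        m = m.select_samples(ann["sample_id"])
    if np.isnan(m.values).any():
        raise ValidationError("beta matrix has missing values; impute first")
    return m.values.T.copy(), ann  # samples x probes


def fit_clock(
    m: BetaMatrix,
    ann: pd.DataFrame,
    transform: AgeTransform | None = None,
    tissue_filter: Iterable[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> ClockModel:
    """Fit an elastic-net clock on raw betas (no standardization).

    The penalty is selected by ``n_folds``-fold internal cross-validation
    minimizing mean squared error over a geometric path of ``N_LAMBDAS``
    candidate strengths.  A constant response yields the degenerate clock
    with zero weights and intercept equal to the common transformed age.
    """
    transform = transform or AgeTransform()
    X, ann_used = _training_arrays(m, ann, tissue_filter)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to fit a clock")
    y = transform.forward(ann_used["age"].to_numpy(),
                          ann_used["species"].to_numpy())
    meta = {
        "alpha": ALPHA,
        "n_training_samples": int(X.shape[0]),
        "tissues": sorted(ann_used["tissue"].unique().tolist()),
        "species": sorted(ann_used["species"].unique().tolist()),
        "seed": int(seed),
        "standardized": False,
    }
    probe_ids = [str(p) for p in m.probe_ids]
    if np.ptp(y) == 0.0:
        meta["lambda"] = None
        return ClockModel({}, float(y[0]), transform, meta)
    n_folds = min(n_folds, X.shape[0])
    if n_folds < 2:
        raise ValidationError("internal CV needs at least 2 folds")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=ALPHA,
        alphas=N_LAMBDAS,
        eps=LAMBDA_MIN_RATIO,
        cv=cv,
        max_iter=5000,
        tol=1e-4,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    meta["lambda"] = float(model.alpha_)
    # sparse map: only probes the penalty kept
    weights = {p: float(w) for p, w in zip(probe_ids, model.coef_) if w != 0.0}
    return ClockModel(weights, float(model.intercept_), transform, meta)


def predict_age(clock: ClockModel, m: BetaMatrix,
                ann: pd.DataFrame) -> pd.DataFrame:
    """Apply a clock: linear score, back-transformed to years.

    Returns one row per sample with ``dnam_age``, ``chronological_age`` and
    ``age_acceleration`` (their difference, in years).
    """
    missing = [p for p in clock.probe_weights if p not in set(m.probe_ids)]
    if missing:
        raise ValidationError(
            f"matrix lacks {len(missing)} clock probes, e.g. {missing[:5]}"
        )
    if np.isnan(m.values).any():
        raise ValidationError("beta matrix has missing values; impute first")
    ann = ann.set_index("sample_id").loc[list(m.sample_ids)].reset_index()
    probe_pos = {str(p): i for i, p in enumerate(m.probe_ids)}
    idx = [probe_pos[p] for p in clock.probe_weights]
    w = np.array(list(clock.probe_weights.values()), dtype=float)
    scores = clock.intercept + w @ m.values[idx, :]
    dnam_age = clock.transform.inverse(scores, ann["species"].to_numpy())
    out = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "species": ann["species"].to_numpy(),
            "tissue": ann["tissue"].to_numpy(),
            "group": ann["group"].to_numpy(),
            "chronological_age": ann["age"].to_numpy(),
            "dnam_age": dnam_age,
        }
    )
    out["age_acceleration"] = out["dnam_age"] - out["chronological_age"]
    return out


def cross_validate(
    m: BetaMatrix,
    ann: pd.DataFrame,
    transform: AgeTransform | None = None,
    scheme: str | int = "loocv",
    tissue_filter: Iterable[str] | None = None,
    seed: int = 0,
) -> CVReport:
    """LOOCV or k-fold cross-validation with full refits per fold.

    Each held-out unit is predicted by a clock fitted from scratch — penalty
    selection included — on the remaining samples; held-out predictions are
    pooled into Pearson R and median absolute error (years).
    """
    transform = transform or AgeTransform()
    X, ann_used = _training_arrays(m, ann, tissue_filter)
    sample_ids = ann_used["sample_id"].to_numpy()
    n = len(sample_ids)
    if n < 3:
        raise ValidationError("cross-validation needs at least 3 samples")
    if scheme == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
        scheme_name = "LOOCV"
    else:
        k = int(scheme)
        if not 2 <= k <= n:
            raise ValidationError(f"k-fold scheme needs 2 <= k <= n, got {k}")
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(kf.split(np.arange(n)))
        scheme_name = f"{k}-fold"

    sub = m.select_samples(sample_ids)
    preds = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for f, (train_idx, test_idx) in enumerate(folds):
        m_train = sub.select_samples(sample_ids[train_idx])
        ann_train = ann_used.iloc[train_idx]
        clock = fit_clock(m_train, ann_train, transform, seed=seed)
        m_test = sub.select_samples(sample_ids[test_idx])
        ann_test = ann_used.iloc[test_idx]
        preds[test_idx] = predict_age(clock, m_test, ann_test)["dnam_age"]
        fold_of[test_idx] = f

    ages = ann_used["age"].to_numpy()
    predictions = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": ann_used["species"].to_numpy(),
            "tissue": ann_used["tissue"].to_numpy(),
            "age": ages,
            "dnam_age": preds,
            "fold": fold_of,
        }
    )
    r = float(np.corrcoef(preds, ages)[0, 1])
    mae = float(np.median(np.abs(preds - ages)))
    return CVReport(scheme_name, predictions, r, mae, int(seed))


def save_clock(clock: ClockModel, path) -> None:
    """Write coefficients as CSV (term,weight) plus a JSON sidecar."""
    path = str(path)
    rows = [("(Intercept)", clock.intercept)]
    rows += [(p, w) for p, w in clock.probe_weights.items() if w != 0.0]
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows, columns=["term", "weight"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = {
        "format_version": 1,
        "transform": clock.transform.kind,
        "max_lifespan_by_species": dict(clock.transform.max_lifespan_by_species),
        "training_meta": clock.training_meta,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_clock(path) -> ClockModel:
    path = str(path)
    coef = pd.read_csv(path, float_precision="round_trip")
    if list(coef.columns) != ["term", "weight"] or coef.empty:
        raise ValidationError(f"malformed clock coefficient file {path}")
    if coef.iloc[0]["term"] != "(Intercept)":
        raise ValidationError("first coefficient row must be (Intercept)")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format_version") != 1:
        raise ValidationError("unsupported clock file version")
    transform = AgeTransform(
        sidecar["transform"], sidecar["max_lifespan_by_species"]
    )
    weights = {
        str(row["term"]): float(row["weight"])
        for _, row in coef.iloc[1:].iterrows()
    }
    return ClockModel(weights, float(coef.iloc[0]["weight"]), transform,
                      sidecar.get("training_meta", {}))
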
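"""Reading, validation and QC of methylation beta matrices and sample sheets.

A beta matrix holds per-CpG methylation fractions (methylated / total signal)
in [0, 1], one row per probe and one column per sample.  Sample sheets carry
the covariates the downstream clocks and EWAS need: species, tissue,
chronological age in years, sex, array batch identifiers, treatment group,
and (for longitudinal designs) subject and timepoint.

On-disk formats are plain text: TSV for matrices (first column ``probe_id``,
missing cells empty or ``NA``) and CSV for sample sheets.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "OutlierReport",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "intersect_probes",
    "impute_missing",
    "flag_outliers",
]

SPECIES = ("rat", "human")
GROUPS = ("young_control", "old_control", "old_treated", "none")

#: columns a sample sheet must provide; the rest default to unknown/none
REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "species", "tissue", "age")
OPTIONAL_ANNOTATION_COLUMNS = (
    "sex",
    "batch_plate",
    "batch_column",
    "group",
    "subject_id",
    "timepoint",
)
ANNOTATION_COLUMNS = REQUIRED_ANNOTATION_COLUMNS + OPTIONAL_ANNOTATION_COLUMNS


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclasses.dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``values`` is a float array with NaN marking missing entries; every
    non-missing value must lie in [0, 1].
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            probe_ids=frame.index.to_numpy(dtype=object),
            sample_ids=frame.columns.to_numpy(dtype=object),
            values=frame.to_numpy(dtype=float),
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        wanted = list(sample_ids)
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in wanted]
        return BetaMatrix(self.probe_ids, np.asarray(wanted, dtype=object),
                          self.values[:, idx])

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        wanted = list(probe_ids)
        pos = {p: k for k, p in enumerate(self.probe_ids)}
        missing = [p for p in wanted if p not in pos]
        if missing:
            raise ValidationError(f"unknown probe ids: {missing[:5]}")
        idx = [pos[p] for p in wanted]
        return BetaMatrix(np.asarray(wanted, dtype=object), self.sample_ids,
                          self.values[idx, :])


@dataclasses.dataclass
class OutlierReport:
    sample_id: str
    mean_correlation: float
    flagged: bool


def read_beta_matrix(path, orientation: str = "probes-in-rows") -> BetaMatrix:
    """Read a delimited beta matrix; ``orientation`` covers the transpose."""
    if orientation not in ("probes-in-rows", "samples-in-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""],
                        float_precision="round_trip")
    if orientation == "samples-in-rows":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:  # non-numeric cell
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return BetaMatrix(frame.index.to_numpy(dtype=object),
                      frame.columns.to_numpy(dtype=object), values)


def write_beta_matrix(m: BetaMatrix, path, float_format: str = "%.6g") -> None:
    m.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format=float_format)


def read_sample_annotation(path) -> pd.DataFrame:
    """Read a sample sheet CSV into a typed annotation frame.

    Required columns: sample_id, species, tissue, age (years).  Optional
    columns default to unknown (sex), empty batch, group ``none``, the
    sample's own id (subject_id) and timepoint 0.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str})
    return validate_annotation(frame)


def validate_annotation(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required columns: {missing}")
    frame = frame.copy()
    frame["sample_id"] = frame["sample_id"].astype(str)
    _check_unique(frame["sample_id"], "sample ids")
    frame["age"] = pd.to_numeric(frame["age"], errors="raise").astype(float)
    if (frame["age"] < 0).any():
        bad = frame.loc[frame["age"] < 0, "sample_id"].tolist()
        raise ValidationError(f"negative age for samples {bad[:5]}")
    bad_species = sorted(set(frame["species"]) - set(SPECIES))
    if bad_species:
        raise ValidationError(f"unknown species {bad_species}")
    defaults = {
        "sex": "unknown",
        "batch_plate": "",
        "batch_column": "",
        "group": "none",
        "subject_id": None,
        "timepoint": 0,
    }
    for col, default in defaults.items():
        if col not in frame.columns:
            frame[col] = default
        frame[col] = frame[col].where(~frame[col].isna(), default)
    frame["subject_id"] = frame["subject_id"].where(
        ~frame["subject_id"].isna(), frame["sample_id"]
    )
    bad_groups = sorted(set(frame["group"].astype(str)) - set(GROUPS))
    if bad_groups:
        raise ValidationError(f"unknown treatment groups {bad_groups}")
    return frame[list(ANNOTATION_COLUMNS)].reset_index(drop=True)


def write_sample_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index=False)


def intersect_probes(a: BetaMatrix, b: BetaMatrix) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict two matrices to their shared probes, in ``a``'s probe order.

    Needed to co-analyse panels from array generations with different CpG
    content (e.g. a 40k conserved-CpG panel and a larger rodent panel).
    """
    shared_set = set(a.probe_ids) & set(b.probe_ids)
    if not shared_set:
        raise ValidationError("probe sets are disjoint; nothing to intersect")
    shared = [p for p in a.probe_ids if p in shared_set]
    return a.select_probes(shared), b.select_probes(shared)


def impute_missing(m: BetaMatrix, strategy: str = "per-probe-mean") -> BetaMatrix:
    """Fill missing betas with the probe's mean over observed samples."""
    if strategy != "per-probe-mean":
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    values = m.values.copy()
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return BetaMatrix(m.probe_ids, m.sample_ids, values)
    all_missing = nan_mask.all(axis=1)
    if all_missing.any():
        bad = m.probe_ids[all_missing].tolist()
        raise ValidationError(f"probes with no observed values: {bad[:5]}")
    with np.errstate(invalid="ignore"):
        probe_means = np.nanmean(values, axis=1)
    rows, cols = np.where(nan_mask)
    values[rows, cols] = probe_means[rows]
    return BetaMatrix(m.probe_ids, m.sample_ids, values)


def flag_outliers(m: BetaMatrix, threshold: float = 0.80) -> list[OutlierReport]:
    """Flag samples whose mean Pearson correlation to the cohort is low.

    A deterministic stand-in for dendrogram-based outlier exclusion: for each
    sample the mean pairwise correlation to every other sample is computed
    and compared with ``threshold``.  A constant-valued sample has undefined
    correlations; it is reported with NaN mean correlation and flagged.
    """
    if m.n_samples < 3:
        raise ValidationError("outlier QC needs at least 3 samples")
    if np.isnan(m.values).any():
        raise ValidationError("impute missing values before outlier QC")
    sd = m.values.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m.values.T)
    np.fill_diagonal(corr, np.nan)
    reports = []
    for j, sid in enumerate(m.sample_ids):
        if constant[j]:
            reports.append(OutlierReport(str(sid), float("nan"), True))
            continue
        mean_r = float(np.nanmean(corr[j]))
        reports.append(OutlierReport(str(sid), mean_r, bool(mean_r < threshold)))
    return reports


def correlation_distance(m: BetaMatrix) -> pd.DataFrame:
    """1 - r distance between samples, for external dendrogram export."""
    corr = np.corrcoef(m.values.T)
    return pd.DataFrame(1.0 - corr, index=m.sample_ids, columns=m.sample_ids)


def outlier_report_frame(reports: list[OutlierReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "mean_correlation": [r.mean_correlation for r in reports],
            "flagged": [r.flagged for r in reports],
        }
    )
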
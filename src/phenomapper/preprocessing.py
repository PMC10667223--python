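"""Cohort ingestion and the feature pipeline feeding the topological network.

The analysis operates on 16 pre-procedure clinical features per patient:
demographics (age, sex), the implanted device type, NYHA functional class
(dichotomized III--IV vs I--II), cardiovascular history indicators (atrial
fibrillation, hypertension, diabetes, ischemic etiology, myocardial
infarction, PCI, CABG), renal function (creatinine, GFR) and echo parameters
(LVEF, LV end-diastolic and end-systolic diameters).  Missing entries are
replaced by the column mean and the matrix is Z-score transformed; the
column means and SDs are retained so that exactly the same transform can be
applied to new patients at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical order of the 16 network features.  Fixed: every matrix built by
#: this module uses this column order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "device_type",
    "nyha_34",
    "af",
    "hypertension",
    "dm",
    "ischemic_etiology",
    "mi",
    "pci",
    "cabg",
    "creatinine",
    "gfr",
    "lvef",
    "lvidd",
    "lvids",
)

#: Indicator (0/1) features among the 16.
BINARY_FEATURES: tuple[str, ...] = (
    "sex",
    "device_type",
    "nyha_34",
    "af",
    "hypertension",
    "dm",
    "ischemic_etiology",
    "mi",
    "pci",
    "cabg",
)

CONTINUOUS_FEATURES: tuple[str, ...] = tuple(
    c for c in FEATURE_COLUMNS if c not in BINARY_FEATURES
)

#: Physiological plausibility bounds for continuous features (validation
#: warnings, not hard errors).  Units: age years, creatinine umol/L,
#: GFR mL/min/1.73m2, LVEF %, LV diameters mm.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 110.0),
    "creatinine": (20.0, 1000.0),
    "gfr": (1.0, 150.0),
    "lvef": (5.0, 80.0),
    "lvidd": (25.0, 100.0),
    "lvids": (15.0, 95.0),
}

OUTCOME_COLUMNS: tuple[str, ...] = ("time_years", "event")


class SchemaError(ValueError):
    """Raised when a cohort table violates the expected schema."""


@dataclass
class FeatureMatrix:
    """Numeric n x 16 feature matrix with its transform parameters.

    ``values`` holds the current matrix (raw, imputed, or Z-scored depending
    on the stage); ``missing_mask`` marks entries that were imputed;
    ``column_means``/``column_sds`` are populated by :func:`zscore` and are
    the frozen parameters reused to transform new patients.
    """

    values: np.ndarray
    columns: tuple[str, ...] = FEATURE_COLUMNS
    missing_mask: np.ndarray | None = None
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    patient_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.copy(),
            columns=self.columns,
            missing_mask=None if self.missing_mask is None else self.missing_mask.copy(),
            column_means=None if self.column_means is None else self.column_means.copy(),
            column_sds=None if self.column_sds is None else self.column_sds.copy(),
            patient_ids=None if self.patient_ids is None else self.patient_ids.copy(),
        )


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table CSV and validate it (see :func:`validate_cohort`)."""
    cohort = pd.read_csv(path)
    validate_cohort(cohort)
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def validate_cohort(cohort: pd.DataFrame, require_outcome: bool = True) -> None:
    """Validate ids, indicator coding, plausibility bounds and outcomes.

    Raises :class:`SchemaError` for structural problems; out-of-bounds
    continuous values only produce warnings.
    """
    if "patient_id" not in cohort.columns:
        raise SchemaError("cohort table lacks a 'patient_id' column")
    if cohort["patient_id"].duplicated().any():
        dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id values: {dupes[:5]}")
    missing_cols = [c for c in FEATURE_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise SchemaError(f"missing feature columns: {missing_cols}")
    for col in BINARY_FEATURES:
        vals = cohort[col].dropna().unique()
        bad = [v for v in vals if v not in (0, 1, 0.0, 1.0, True, False)]
        if bad:
            raise SchemaError(
                f"indicator column {col!r} contains non-binary values: {bad[:5]}"
            )
    for col, (lo, hi) in PLAUSIBILITY_BOUNDS.items():
        vals = cohort[col].dropna()
        n_out = int(((vals < lo) | (vals > hi)).sum())
        if n_out:
            warnings.warn(
                f"{n_out} value(s) of {col!r} outside plausibility bounds [{lo}, {hi}]",
                stacklevel=2,
            )
    if require_outcome:
        missing_outcome = [c for c in OUTCOME_COLUMNS if c not in cohort.columns]
        if missing_outcome:
            raise SchemaError(f"missing outcome columns: {missing_outcome}")
        if cohort[list(OUTCOME_COLUMNS)].isna().any().any():
            raise SchemaError("outcome columns must never be missing")
        if (cohort["time_years"] < 0).any():
            raise SchemaError("time_years must be non-negative")
        if not cohort["event"].isin([0, 1]).all():
            raise SchemaError("event must be 0/1")


def encode_nyha(series: pd.Series) -> pd.Series:
    """Convert an ordinal NYHA class (1..4 or 'I'..'IV') to the III-IV indicator."""
    roman = {"I": 1, "II": 2, "III": 3, "IV": 4}
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, str):
            v = roman.get(v.strip().upper(), v)
        return 1.0 if float(v) >= 3 else 0.0
    return series.map(conv)


def encode_features(cohort: pd.DataFrame) -> FeatureMatrix:
    """Extract the 16 features in canonical order as a raw numeric matrix.

    An ordinal ``nyha_class`` column (I-IV) is accepted in place of the
    ``nyha_34`` indicator and dichotomized at III.  Missing entries remain
    NaN; the missing mask is recorded.
    """
    cohort = cohort.copy()
    if "nyha_34" not in cohort.columns and "nyha_class" in cohort.columns:
        cohort["nyha_34"] = encode_nyha(cohort["nyha_class"])
    validate_cohort(cohort, require_outcome=False)
    values = cohort[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    return FeatureMatrix(
        values=values,
        missing_mask=np.isnan(values),
        patient_ids=cohort["patient_id"].to_numpy(),
    )


def impute_mean(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing entry by its column's observed mean.

    Observed entries are untouched; the missing mask is preserved so later
    stages know what was filled in.
    """
    out = matrix.copy()
    X = out.values
    mask = np.isnan(X)
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        names = [out.columns[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"cannot impute fully-missing column(s): {names}")
    col_means = np.nanmean(X, axis=0)
    X[mask] = np.take(col_means, np.nonzero(mask)[1])
    out.missing_mask = mask
    return out


def zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score transform each column: (x - mean) / sd with sample (n-1) SD.

    Constant columns map to zero with a warning.  The means and SDs are
    stored on the result for application to held-out patients.
    """
    out = matrix.copy()
    X = out.values
    if np.isnan(X).any():
        raise ValueError("zscore requires an imputed (complete) matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = sds == 0
    if constant.any():
        names = [out.columns[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant feature column(s) map to 0: {names}", stacklevel=2)
    safe_sds = np.where(constant, 1.0, sds)
    out.values = (X - means) / safe_sds
    out.values[:, constant] = 0.0
    out.column_means = means
    out.column_sds = sds
    return out


def apply_transform(new: FeatureMatrix, fitted: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted impute+Z-score transform to new patients.

    Missing entries are filled with the *fitted* column means and the fitted
    means/SDs standardize the result — the new data never updates the
    transform.
    """
    if fitted.column_means is None or fitted.column_sds is None:
        raise ValueError("fitted matrix has no stored transform parameters")
    out = new.copy()
    X = out.values
    mask = np.isnan(X)
    X[mask] = np.take(fitted.column_means, np.nonzero(mask)[1])
    constant = fitted.column_sds == 0
    safe_sds = np.where(constant, 1.0, fitted.column_sds)
    out.values = (X - fitted.column_means) / safe_sds
    out.values[:, constant] = 0.0
    out.missing_mask = mask
    out.column_means = fitted.column_means.copy()
    out.column_sds = fitted.column_sds.copy()
    return out


def preprocess(cohort: pd.DataFrame) -> FeatureMatrix:
    """Full pipeline: encode -> mean-impute -> Z-score."""
    return zscore(impute_mean(encode_features(cohort)))
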
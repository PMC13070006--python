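"""Data model and CSV I/O for longitudinal RNFL cohorts.

A cohort joins two tables:

* ``measurements`` — long format, one row per (subject, visit, sector)
  peripapillary RNFL thickness observation in μm.  Sector is a clock hour
  1..12, or the special global sector (the average over the full scan
  circle), held internally as :data:`GLOBAL_SECTOR`.
* ``covariates`` — wide format, one row per subject with the baseline
  demographic and clinical predictors.

Both tables are plain UTF-8 CSVs so that every number in an analysis can be
inspected with a text editor.  Validation is strict: the loader rejects
malformed files with typed exceptions rather than propagating NaNs into the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DimensionError,
    SchemaError,
    UniquenessError,
)

#: Sector code used for the global (full-circle) average.
GLOBAL_SECTOR = 0

#: Number of A-scan samples on the peripapillary circle.
N_ASCANS = 768

#: Number of clock-hour sectors.
N_SECTORS = 12

MEASUREMENT_COLUMNS = [
    "subject_id",
    "eye",
    "t_years",
    "sector",
    "thickness_um",
    "quality",
    "excluded",
    "exclusion_reason",
]

COVARIATE_COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "ethnicity",
    "dbp_mmhg",
    "sbp_mmhg",
    "iop_mmhg",
    "cct_um",
    "axial_length_mm",
    "cs12",
    "md_db",
    "diabetes",
    "hypertension",
    "bp_medication",
    "beta_blocker",
]

NUMERIC_COVARIATES = [
    "age_years",
    "dbp_mmhg",
    "sbp_mmhg",
    "iop_mmhg",
    "cct_um",
    "axial_length_mm",
    "cs12",
    "md_db",
]

BINARY_COVARIATES = ["diabetes", "hypertension", "bp_medication", "beta_blocker"]

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("White", "Black", "Hispanic", "Asian")
EYES = ("OD", "OS")
EXCLUSION_REASONS = ("none", "quality", "outlier")

#: Tolerance for the global-equals-mean-of-sectors consistency check (μm).
GLOBAL_MEAN_TOL = 1e-6


@dataclass
class AScanProfile:
    """One raw 768-sample peripapillary thickness profile at one visit."""

    subject_id: str
    eye: str
    t: float
    values: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ASCANS,):
            raise DimensionError(
                f"A-scan profile must have exactly {N_ASCANS} samples, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ConsistencyError("A-scan samples must be positive and finite")


@dataclass
class Cohort:
    """Validated longitudinal cohort: measurements + baseline covariates.

    ``metadata`` carries provenance and the cumulative filter log written by
    the preprocessing steps.
    """

    measurements: pd.DataFrame
    covariates: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def retained_measurements(self) -> pd.DataFrame:
        """Measurement rows not flagged as excluded."""
        return self.measurements[~self.measurements["excluded"]]

    def copy(self) -> "Cohort":
        import copy as _copy

        return Cohort(
            self.measurements.copy(),
            self.covariates.copy(),
            _copy.deepcopy(self.metadata),
        )

    def validate(self) -> "Cohort":
        _validate_measurements(self.measurements)
        _validate_covariates(self.covariates)
        m_subj = set(self.measurements["subject_id"])
        c_subj = set(self.covariates["subject_id"])
        if m_subj != c_subj:
            missing = sorted(m_subj ^ c_subj)
            raise ConsistencyError(
                f"subject mismatch between measurements and covariates: {missing}"
            )
        return self


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _validate_measurements(df: pd.DataFrame) -> None:
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements table")
    bad_eye = set(df["eye"]) - set(EYES)
    if bad_eye:
        raise ConsistencyError(f"invalid eye codes: {sorted(bad_eye)}")
    eyes_per_subject = df.groupby("subject_id")["eye"].nunique()
    multi = eyes_per_subject[eyes_per_subject > 1]
    if len(multi):
        raise ConsistencyError(
            f"more than one eye per subject: {list(multi.index)}"
        )
    t = df["t_years"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ConsistencyError("t_years must be finite and >= 0")
    th = df["thickness_um"].to_numpy(dtype=float)
    if not np.all(np.isfinite(th)) or np.any(th <= 0):
        raise ConsistencyError("thickness_um must be positive and finite")
    sectors = df["sector"].to_numpy()
    valid = set(range(N_SECTORS + 1))  # 0 == GLOBAL
    bad = set(sectors) - valid
    if bad:
        raise ConsistencyError(f"invalid sector codes: {sorted(bad)}")
    bad_reason = set(df["exclusion_reason"]) - set(EXCLUSION_REASONS)
    if bad_reason:
        raise ConsistencyError(f"invalid exclusion reasons: {sorted(bad_reason)}")
    dup = df.duplicated(subset=["subject_id", "t_years", "sector"])
    if dup.any():
        rows = df.loc[dup, ["subject_id", "t_years", "sector"]].head()
        raise UniquenessError(
            f"duplicate (subject, visit, sector) records, e.g.\n{rows}"
        )
    _check_global_mean(df)


def _check_global_mean(df: pd.DataFrame) -> None:
    """Where a visit carries both a global row and all 12 sector rows, the
    global value must equal the mean of the sectors to GLOBAL_MEAN_TOL."""
    for (subj, t), grp in df.groupby(["subject_id", "t_years"], sort=False):
        sect = grp[grp["sector"] != GLOBAL_SECTOR]
        glob = grp[grp["sector"] == GLOBAL_SECTOR]
        if len(glob) and len(sect) == N_SECTORS:
            expected = sect["thickness_um"].mean()
            actual = float(glob["thickness_um"].iloc[0])
            if abs(actual - expected) > GLOBAL_MEAN_TOL:
                raise ConsistencyError(
                    f"global thickness {actual:.6f} != mean of sectors "
                    f"{expected:.6f} for subject {subj} at t={t}"
                )


def _validate_covariates(df: pd.DataFrame) -> None:
    _require_columns(df, COVARIATE_COLUMNS, "covariates table")
    if df["subject_id"].duplicated().any():
        raise UniquenessError("duplicate subject_id in covariates table")
    bad_sex = set(df["sex"]) - set(SEX_LEVELS)
    if bad_sex:
        raise ConsistencyError(f"invalid sex levels: {sorted(bad_sex)}")
    bad_eth = set(df["ethnicity"]) - set(ETHNICITY_LEVELS)
    if bad_eth:
        raise ConsistencyError(f"invalid ethnicity levels: {sorted(bad_eth)}")
    for col in NUMERIC_COVARIATES:
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConsistencyError(f"non-finite values in covariate {col!r}")
    if np.any(df["dbp_mmhg"].to_numpy(float) >= df["sbp_mmhg"].to_numpy(float)):
        raise ConsistencyError("diastolic BP must be strictly below systolic BP")
    for col in BINARY_COVARIATES:
        vals = set(pd.Series(df[col]).astype(int))
        if not vals <= {0, 1}:
            raise ConsistencyError(f"covariate {col!r} must be 0/1")


def _sector_to_str(s: int) -> str:
    return "G" if s == GLOBAL_SECTOR else str(int(s))


def _sector_from_str(s) -> int:
    s = str(s).strip()
    if s.upper() == "G":
        return GLOBAL_SECTOR
    try:
        val = int(s)
    except ValueError as exc:
        raise ConsistencyError(f"invalid sector code {s!r}") from exc
    return val


def load_cohort(measurements_path, covariates_path) -> Cohort:
    """Load and validate a cohort from the two CSV files.

    Raises :class:`SchemaError` for missing columns,
    :class:`UniquenessError` for duplicate records and
    :class:`ConsistencyError` for cross-field violations.
    """
    measurements_path = Path(measurements_path)
    covariates_path = Path(covariates_path)
    meas = pd.read_csv(measurements_path, dtype={"subject_id": str},
                       float_precision="round_trip")
    _require_columns(meas, MEASUREMENT_COLUMNS, "measurements table")
    meas["sector"] = [_sector_from_str(s) for s in meas["sector"]]
    meas["t_years"] = meas["t_years"].astype(float)
    meas["thickness_um"] = meas["thickness_um"].astype(float)
    meas["quality"] = meas["quality"].astype(float)
    meas["excluded"] = meas["excluded"].astype(bool)
    meas["exclusion_reason"] = (
        meas["exclusion_reason"].fillna("none").replace("", "none").astype(str)
    )
    cov = pd.read_csv(covariates_path, dtype={"subject_id": str},
                      float_precision="round_trip")
    _require_columns(cov, COVARIATE_COLUMNS, "covariates table")
    for col in BINARY_COVARIATES:
        cov[col] = cov[col].astype(int)
    cohort = Cohort(
        meas.reset_index(drop=True),
        cov.reset_index(drop=True),
        metadata={
            "source": {
                "measurements": str(measurements_path),
                "covariates": str(covariates_path),
            }
        },
    )
    return cohort.validate()


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write ``measurements.csv`` and ``covariates.csv`` under ``out_dir``.

    Returns the mapping of table name to written path.  Floats are written
    with shortest round-trip repr, so ``load_cohort`` recovers them exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meas = cohort.measurements.copy()
    meas["sector"] = [_sector_to_str(s) for s in meas["sector"]]
    meas_path = out_dir / "measurements.csv"
    meas.to_csv(meas_path, index=False, columns=MEASUREMENT_COLUMNS)
    cov_path = out_dir / "covariates.csv"
    cohort.covariates.to_csv(cov_path, index=False, columns=COVARIATE_COLUMNS)
    return {"measurements": meas_path, "covariates": cov_path}


def load_ascan_profiles(path) -> list[AScanProfile]:
    """Read 768-sample A-scan profiles from the wide CSV stand-in for the
    instrument's XML export (columns v0..v767)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    vcols = [f"v{i}" for i in range(N_ASCANS)]
    _require_columns(df, ["subject_id", "eye", "t_years", "quality"] + vcols,
                     "ascan_profiles table")
    out = []
    values = df[vcols].to_numpy(dtype=float)
    for i, row in df.iterrows():
        out.append(
            AScanProfile(
                subject_id=row["subject_id"],
                eye=row["eye"],
                t=float(row["t_years"]),
                values=values[i],
                quality=float(row["quality"]),
            )
        )
    return out
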
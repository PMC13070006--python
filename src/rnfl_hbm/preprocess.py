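"""Preprocessing: sectors, quality/eligibility filters, outliers, standardization.

Everything between raw measurement records and the model's design inputs:

* averaging 768-sample A-scan profiles into 12 clock-hour sectors + global;
* flagging scans below the quality-score floor;
* dropping subjects with too few scans or too little follow-up;
* iterative removal of within-series outliers by externally studentized
  residuals from per-series ordinary least squares lines;
* standardizing covariates (numeric, binary indicators, ethnicity dummies
  against a White reference) to mean 0 / SD 1, with an optional BP×IOP
  interaction column built as the re-standardized product of the
  standardized components.

Filters never delete measurement rows (except whole-subject eligibility
removal); they set the ``excluded`` flag with a reason so that every
decision stays auditable in the written CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    GLOBAL_SECTOR,
    N_ASCANS,
    N_SECTORS,
    AScanProfile,
    Cohort,
)
from .errors import (
    DegenerateCovariateError,
    DimensionError,
    EmptyCohortError,
    NamingError,
)

DEFAULT_MIN_QUALITY = 15.0
DEFAULT_MIN_SCANS = 4
DEFAULT_MIN_YEARS = 2.0
DEFAULT_Z_THRESHOLD = 3.1
DEFAULT_MAX_ITER = 3

#: Prior degrees of freedom pulling each series' residual variance toward
#: the cohort-wide (median) level when studentizing outlier candidates.
DEFAULT_PRIOR_DF = 10.0

#: Encoded (numeric) covariate names in report order, before BP/IOP terms.
ENCODED_COVARIATES = [
    "age",
    "sex_female",
    "eth_black",
    "eth_hispanic",
    "eth_asian",
    "hypertension",
    "bp_medication",
    "diabetes",
    "cct",
    "axial_length",
    "cs12",
    "md",
    "beta_blocker",
    "iop",
    "dbp",
    "sbp",
]

_RAW_TO_ENCODED = {
    "age_years": "age",
    "cct_um": "cct",
    "axial_length_mm": "axial_length",
    "cs12": "cs12",
    "md_db": "md",
    "iop_mmhg": "iop",
    "dbp_mmhg": "dbp",
    "sbp_mmhg": "sbp",
}


# ---------------------------------------------------------------------------
# Sector computation


def sector_thickness(profile: AScanProfile | np.ndarray):
    """Average a 768-sample profile into 12 clock-hour sectors + global.

    Sector ``j`` (1-based) is the mean of the j-th contiguous block of 64
    A-scans; the global thickness is the mean of all 768 samples, which by
    construction equals the mean of the 12 sector means.

    Returns ``(sectors, global_mean)`` with ``sectors`` of shape (12,).
    """
    values = profile.values if isinstance(profile, AScanProfile) else np.asarray(
        profile, dtype=float
    )
    if values.shape != (N_ASCANS,):
        raise DimensionError(
            f"expected {N_ASCANS} A-scan samples, got {values.size}"
        )
    sectors = values.reshape(N_SECTORS, N_ASCANS // N_SECTORS).mean(axis=1)
    return sectors, float(values.mean())


def profiles_to_measurements(profiles: list[AScanProfile]) -> pd.DataFrame:
    """Convert A-scan profiles to long-format sector measurement rows."""
    rows = []
    for p in profiles:
        sectors, g = sector_thickness(p)
        for j, th in enumerate(sectors, start=1):
            rows.append((p.subject_id, p.eye, p.t, j, th, p.quality))
        rows.append((p.subject_id, p.eye, p.t, GLOBAL_SECTOR, g, p.quality))
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "eye", "t_years", "sector", "thickness_um", "quality"],
    )
    df["excluded"] = False
    df["exclusion_reason"] = "none"
    return df


# ---------------------------------------------------------------------------
# Quality and eligibility filters


def _log(cohort: Cohort, key: str, entry: dict) -> None:
    cohort.metadata.setdefault("filter_log", {})[key] = entry


def filter_quality(cohort: Cohort, min_quality: float = DEFAULT_MIN_QUALITY) -> Cohort:
    """Flag every record of scans with quality score below ``min_quality``.

    The bound is inclusive: a scan at exactly the floor is retained.
    """
    out = cohort.copy()
    meas = out.measurements
    bad = (meas["quality"] < min_quality) & ~meas["excluded"]
    meas.loc[bad, "excluded"] = True
    meas.loc[bad, "exclusion_reason"] = "quality"
    _log(out, "quality", {
        "min_quality": float(min_quality),
        "records_flagged": int(bad.sum()),
    })
    return out


def filter_eligibility(
    cohort: Cohort,
    min_scans: int = DEFAULT_MIN_SCANS,
    min_years: float = DEFAULT_MIN_YEARS,
) -> Cohort:
    """Remove subjects with < ``min_scans`` retained scans or < ``min_years``
    of follow-up (both bounds inclusive).  Quality filtering should already
    have been applied so that flagged scans do not count.
    """
    out = cohort.copy()
    retained = out.retained_measurements()
    keep = []
    for subj, grp in retained.groupby("subject_id"):
        times = np.unique(grp["t_years"].to_numpy(float))
        n_scans = len(times)
        span = float(times.max() - times.min()) if n_scans else 0.0
        if n_scans >= min_scans and span >= min_years:
            keep.append(subj)
    removed = sorted(set(out.subjects) - set(keep))
    if not keep:
        raise EmptyCohortError(
            "no subjects meet the eligibility criteria "
            f"(min_scans={min_scans}, min_years={min_years})"
        )
    out.measurements = out.measurements[
        out.measurements["subject_id"].isin(keep)
    ].reset_index(drop=True)
    out.covariates = out.covariates[
        out.covariates["subject_id"].isin(keep)
    ].reset_index(drop=True)
    _log(out, "eligibility", {
        "min_scans": int(min_scans),
        "min_years": float(min_years),
        "subjects_removed": removed,
        "subjects_retained": len(keep),
    })
    return out


# ---------------------------------------------------------------------------
# Outlier detection


def _studentized_residuals(
    t: np.ndarray,
    y: np.ndarray,
    pooled_var: float | None = None,
    prior_df: float = 0.0,
) -> np.ndarray:
    """(Moderated) externally studentized residuals of a straight-line fit.

    Closed-form leave-one-out formulas: with hat values
    h_i = 1/n + (t_i - t̄)²/S_tt and residuals e_i, the deleted variance is
    s_(i)² = ((n-2)s² - e_i²/(1-h_i)) / (n-3); requires n ≥ 4.  With
    ``pooled_var``/``prior_df`` set, the deleted variance is shrunk toward
    the cohort-wide level, s̃² = (d₀·s₀² + (n-3)·s_(i)²) / (d₀ + n-3): the
    handful of residual degrees of freedom in one short series make the
    plain estimator too noisy to separate large spikes from quiet series.
    With ``prior_df=0`` this is the classical externally studentized
    residual.
    """
    n = t.size
    tbar = t.mean()
    dt = t - tbar
    stt = float(dt @ dt)
    slope = float(dt @ y) / stt
    intercept = y.mean() - slope * tbar
    e = y - intercept - slope * t
    h = 1.0 / n + dt**2 / stt
    sse = float(e @ e)
    denom = sse - e**2 / (1.0 - h)
    denom = np.maximum(denom, 0.0) / (n - 3)
    if pooled_var is not None and prior_df > 0:
        denom = (prior_df * pooled_var + (n - 3) * denom) / (prior_df + n - 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = e / np.sqrt(denom * (1.0 - h))
    # zero deleted variance: an exact fit elsewhere makes a nonzero residual
    # infinitely surprising, while a zero residual is no outlier at all
    bad = ~np.isfinite(out)
    out[bad] = np.where(np.abs(e[bad]) < 1e-8, 0.0, np.inf * np.sign(e[bad]))
    return out


def _series_residual_variance(t: np.ndarray, y: np.ndarray) -> float:
    n = t.size
    dt = t - t.mean()
    stt = float(dt @ dt)
    slope = float(dt @ y) / stt
    e = y - (y.mean() - slope * t.mean()) - slope * t
    return float(e @ e) / (n - 2)


def detect_outliers(
    cohort: Cohort,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> Cohort:
    """Iteratively flag within-series outliers by studentized residuals.

    For every retained (subject, sector) series of clock-hour measurements a
    straight line is fit by OLS; the single observation with the largest
    absolute moderated externally studentized residual is flagged if it
    exceeds ``z_threshold``; the line is refit and the step repeated up to
    ``max_iter`` times.  Studentization shrinks each series' residual
    variance toward the cohort-wide median level with ``prior_df`` prior
    degrees of freedom (``prior_df=0`` recovers the classical per-series
    statistic).  A series is never reduced below 3 points, and series
    shorter than 3 points are skipped (recorded in the log).  Exact ties in
    the residual magnitude are broken toward the earliest visit.

    Flagged rows get ``exclusion_reason == "outlier"``.  The filter log
    records the overall flagged fraction.
    """
    out = cohort.copy()
    meas = out.measurements
    is_sector = meas["sector"] != GLOBAL_SECTOR
    considered = int((is_sector & ~meas["excluded"]).sum())
    flagged_idx: list[int] = []
    skipped: list[tuple] = []
    retained = meas[is_sector & ~meas["excluded"]]
    pooled_var = None
    if prior_df > 0:
        per_series = [
            _series_residual_variance(
                grp["t_years"].to_numpy(float), grp["thickness_um"].to_numpy(float)
            )
            for _, grp in retained.groupby(["subject_id", "sector"], sort=True)
            if len(grp) >= 3
        ]
        # the median is robust to the contaminated minority of series
        pooled_var = float(np.median(per_series)) if per_series else None
        if pooled_var is not None and pooled_var <= 0:
            pooled_var = None
    for (subj, sector), grp in retained.groupby(["subject_id", "sector"], sort=True):
        idx = grp.index.to_numpy()
        t = grp["t_years"].to_numpy(float)
        y = grp["thickness_um"].to_numpy(float)
        order = np.argsort(t, kind="stable")
        idx, t, y = idx[order], t[order], y[order]
        if t.size < 3:
            skipped.append((subj, int(sector), int(t.size)))
            continue
        alive = np.ones(t.size, dtype=bool)
        for _ in range(max_iter):
            if alive.sum() < 4:  # removal would drop the series below 3 points
                break
            resid = _studentized_residuals(t[alive], y[alive],
                                           pooled_var, prior_df)
            absr = np.abs(resid)
            top = absr.max()
            if top <= z_threshold:
                break
            # earliest-visit tie-break; t is sorted so argmax returns it
            local = int(np.argmax(absr))
            global_pos = np.flatnonzero(alive)[local]
            alive[global_pos] = False
            flagged_idx.append(int(idx[global_pos]))
    if flagged_idx:
        meas.loc[flagged_idx, "excluded"] = True
        meas.loc[flagged_idx, "exclusion_reason"] = "outlier"
    fraction = len(flagged_idx) / considered if considered else 0.0
    _log(out, "outliers", {
        "z_threshold": float(z_threshold),
        "max_iter": int(max_iter),
        "prior_df": float(prior_df),
        "records_flagged": len(flagged_idx),
        "records_considered": considered,
        "flagged_fraction": fraction,
        "skipped_series": [
            {"subject_id": s, "sector": j, "n": n} for s, j, n in skipped
        ],
    })
    return out


# ---------------------------------------------------------------------------
# Covariate standardization


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the raw covariate table.

    Sex becomes a female indicator, ethnicity becomes three indicators with
    White as reference, booleans become 0/1; numeric columns are renamed to
    their short model names.  Index is subject_id.
    """
    enc = pd.DataFrame(index=covariates["subject_id"])
    for raw, name in _RAW_TO_ENCODED.items():
        enc[name] = covariates[raw].to_numpy(float)
    enc["sex_female"] = (covariates["sex"] == "female").astype(float).to_numpy()
    for level in ("Black", "Hispanic", "Asian"):
        enc[f"eth_{level.lower()}"] = (
            (covariates["ethnicity"] == level).astype(float).to_numpy()
        )
    for col in ("diabetes", "hypertension", "bp_medication", "beta_blocker"):
        enc[col] = covariates[col].astype(float).to_numpy()
    return enc[ENCODED_COVARIATES]


@dataclass
class StandardizationMap:
    """Means/SDs used to z-score covariates, plus the interaction rule.

    ``interaction`` is ``None`` or a tuple ``(a, b, name)`` meaning the
    column ``name`` is the product of the standardized columns ``a`` and
    ``b``, itself re-centered by ``product_mean`` and re-scaled by
    ``product_sd``.  All constants are retained so coefficients can be
    back-transformed to raw covariate scales.
    """

    columns: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    interaction: tuple[str, str, str] | None = None
    product_mean: float = 0.0
    product_sd: float = 1.0
    ddof: int = 1

    @property
    def output_columns(self) -> list[str]:
        cols = list(self.columns)
        if self.interaction is not None:
            cols.append(self.interaction[2])
        return cols

    def transform(self, encoded: pd.DataFrame) -> pd.DataFrame:
        for col in self.columns:
            if col not in encoded.columns:
                raise NamingError(f"covariate {col!r} absent from input")
        z = pd.DataFrame(index=encoded.index)
        for col in self.columns:
            z[col] = (encoded[col].to_numpy(float) - self.means[col]) / self.sds[col]
        if self.interaction is not None:
            a, b, name = self.interaction
            prod = z[a].to_numpy() * z[b].to_numpy()
            z[name] = (prod - self.product_mean) / self.product_sd
        return z

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        raw = pd.DataFrame(index=z.index)
        for col in self.columns:
            raw[col] = z[col].to_numpy(float) * self.sds[col] + self.means[col]
        return raw


def standardize_covariates(
    covariates: pd.DataFrame,
    columns: list[str],
    interaction: tuple[str, str] | None = None,
    ddof: int = 1,
):
    """Z-score the requested encoded covariate columns over subjects.

    Sample SD uses the ``n-1`` denominator by default.  The interaction
    column, when requested, is the elementwise product of the two
    standardized components, re-centered and re-scaled to mean 0 / SD 1.

    Returns ``(StandardizationMap, z_frame)``.  Raises
    :class:`DegenerateCovariateError` for zero-variance covariates and
    :class:`NamingError` for unknown columns.
    """
    encoded = (
        encode_covariates(covariates)
        if "age_years" in covariates.columns
        else covariates
    )
    for col in columns:
        if col not in encoded.columns:
            raise NamingError(f"unknown covariate {col!r}")
    means, sds = {}, {}
    for col in columns:
        vals = encoded[col].to_numpy(float)
        m = float(vals.mean())
        s = float(vals.std(ddof=ddof))
        if not s > 0:
            raise DegenerateCovariateError(
                f"covariate {col!r} has zero variance and cannot be standardized"
            )
        means[col], sds[col] = m, s
    smap = StandardizationMap(columns=list(columns), means=means, sds=sds, ddof=ddof)
    if interaction is not None:
        a, b = interaction
        if a not in columns or b not in columns:
            raise NamingError(
                f"interaction components {interaction} must be standardized columns"
            )
        za = (encoded[a].to_numpy(float) - means[a]) / sds[a]
        zb = (encoded[b].to_numpy(float) - means[b]) / sds[b]
        prod = za * zb
        pm = float(prod.mean())
        ps = float(prod.std(ddof=ddof))
        if not ps > 0:
            raise DegenerateCovariateError("interaction product has zero variance")
        smap.interaction = (a, b, f"{a}_x_{b}")
        smap.product_mean = pm
        smap.product_sd = ps
    return smap, smap.transform(encoded)


# ---------------------------------------------------------------------------
# Design inputs


@dataclass
class DesignInputs:
    """Model-ready inputs: standardized covariates + filtered series.

    ``series`` holds, per retained (subject, sector) series, the observation
    times and thicknesses that survived all filters; ``z`` is the subjects ×
    covariates standardized design frame (interaction column included when
    requested).
    """

    subjects: list
    z: pd.DataFrame
    smap: StandardizationMap
    series_subject: np.ndarray   # (S,) int index into subjects
    series_sector: np.ndarray    # (S,) int 0..11
    series_t: list[np.ndarray]
    series_y: list[np.ndarray]
    filter_log: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_series(self) -> int:
        return len(self.series_t)

    @property
    def n_obs(self) -> int:
        return int(sum(len(t) for t in self.series_t))


def build_design(
    cohort: Cohort,
    columns: list[str],
    interaction: tuple[str, str] | None = None,
) -> DesignInputs:
    """Assemble :class:`DesignInputs` from a filtered cohort.

    Uses retained clock-hour records only (the global series is a derived
    summary and never enters the model).  Series left with fewer than 2
    observations are dropped and logged.
    """
    encoded = encode_covariates(cohort.covariates)
    smap, z = standardize_covariates(encoded, columns, interaction=interaction)
    subjects = list(cohort.covariates["subject_id"])
    subj_index = {s: i for i, s in enumerate(subjects)}
    retained = cohort.retained_measurements()
    retained = retained[retained["sector"] != GLOBAL_SECTOR]
    s_subj, s_sect, s_t, s_y = [], [], [], []
    dropped = []
    for (subj, sector), grp in retained.groupby(["subject_id", "sector"], sort=True):
        t = grp["t_years"].to_numpy(float)
        y = grp["thickness_um"].to_numpy(float)
        if t.size < 2:
            dropped.append({"subject_id": subj, "sector": int(sector), "n": int(t.size)})
            continue
        order = np.argsort(t, kind="stable")
        s_subj.append(subj_index[subj])
        s_sect.append(int(sector) - 1)
        s_t.append(t[order])
        s_y.append(y[order])
    log = dict(cohort.metadata.get("filter_log", {}))
    log["design"] = {"series_dropped_short": dropped, "n_series": len(s_t)}
    return DesignInputs(
        subjects=subjects,
        z=z.loc[subjects],
        smap=smap,
        series_subject=np.asarray(s_subj, dtype=int),
        series_sector=np.asarray(s_sect, dtype=int),
        series_t=s_t,
        series_y=s_y,
        filter_log=log,
    )
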
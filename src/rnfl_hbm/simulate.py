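"""Synthetic RNFL cohort generator with known ground truth.

Emulates a glaucoma cohort of ~110 eyes followed with semiannual
peripapillary OCT for ~4.3 years: baseline covariates are drawn from the
study-population marginals (age 66.7 ± 8.6 y, DBP 81.9 ± 10.3 mmHg,
SBP 135.2 ± 18.1 mmHg, medicated IOP 12.6 ± 3.9 mmHg, …), and sector
thickness trajectories follow exactly the hierarchical growth model the
package fits — subject- and sector-level bivariate random
intercepts/slopes, log-normal residual SDs, and standardized covariate
effects on baseline and rate of change, including a BP×IOP interaction.

Covariate effects are planted on the *realized* standardized scale: the
generator standardizes its drawn covariates with the same routine the
preprocessing uses, so the ground-truth coefficients are exactly the
estimands of a model fit to the generated data.  Every latent draw is
returned in a :class:`GroundTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GLOBAL_SECTOR, N_SECTORS, Cohort
from .errors import ConfigError
from .preprocess import encode_covariates, standardize_covariates

_J = np.arange(N_SECTORS)

#: Default sector-level population intercepts (μm): a double-hump profile
#: (superior/inferior bundles) with global mean exactly 62.2.
DEFAULT_MU_ALPHA = 62.2 + 14.0 * np.cos(4 * np.pi * (_J + 0.5) / N_SECTORS)

#: Default sector-level population slopes (μm/year), global mean −0.28.
DEFAULT_MU_BETA = -0.28 + 0.08 * np.cos(2 * np.pi * (_J + 0.5) / N_SECTORS)

#: Default numeric covariate marginals: mean, SD.
DEFAULT_MARGINALS = {
    "age": (66.7, 8.6),
    "dbp": (81.9, 10.3),
    "sbp": (135.2, 18.1),
    "iop": (12.6, 3.9),
    "cct": (534.3, 40.2),
    "axial_length": (24.6, 1.45),
    "cs12": (3.9, 1.8),
    "md": (-8.8, 6.0),
}

#: Default covariate effects on the standardized scale.  Baseline (δ) in
#: μm per SD; rate of change (γ) in μm/year per SD.  Zeros are genuine
#: nulls kept for shrinkage behaviour checks.
DEFAULT_DELTA = {"md": 3.0, "sex_female": -1.5}
DEFAULT_GAMMA = {
    "iop": -0.3,
    "dbp": -0.12,
    "dbp_x_iop": 0.3,
    "md": -0.1,
    "cs12": -0.1,
    "age": 0.0,
    "sex_female": 0.0,
    "diabetes": 0.0,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults emulate the study cohort."""

    n_subjects: int = 110
    visits_mean: float = 8.3
    visits_sd: float = 1.4
    min_visits: int = 4
    followup_mean: float = 4.3
    followup_sd: float = 0.5
    visit_interval: float = 0.5
    visit_jitter_sd: float = 0.05

    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    p_female: float = 0.618
    p_diabetes: float = 0.155
    p_hypertension: float = 0.373
    p_bp_medication: float = 0.364
    p_beta_blocker: float = 0.527
    ethnicity_probs: tuple = (0.518, 0.164, 0.118, 0.200)  # W, B, H, A
    bp_iop_correlation: float = 0.0

    mu_alpha: np.ndarray = field(default_factory=lambda: DEFAULT_MU_ALPHA.copy())
    mu_beta: np.ndarray = field(default_factory=lambda: DEFAULT_MU_BETA.copy())
    tau_alpha: float = 5.0
    tau_beta: float = 0.25
    rho_sector: float = 0.2
    sd_subject_intercept: float = 12.5
    sd_subject_slope: float = 0.25
    rho_subject: float = -0.2
    m_log_sigma: float = float(np.log(2.0))
    s_log_sigma: float = 0.25

    delta: dict = field(default_factory=lambda: dict(DEFAULT_DELTA))
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    interaction: tuple | None = ("dbp", "iop")

    outlier_frac: float = 0.01
    outlier_min_sd: float = 5.0
    outlier_max_sd: float = 8.0
    quality_mean: float = 25.0
    quality_sd: float = 4.0
    low_quality_frac: float = 0.02

    def __post_init__(self):
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=float)
        self.mu_beta = np.asarray(self.mu_beta, dtype=float)
        if self.interaction is not None:
            self.interaction = tuple(self.interaction)
        self.validate()

    def validate(self) -> None:
        probs = [self.p_female, self.p_diabetes, self.p_hypertension,
                 self.p_bp_medication, self.p_beta_blocker,
                 self.low_quality_frac, self.outlier_frac]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.ethnicity_probs) - 1.0) > 1e-9:
            raise ConfigError("ethnicity proportions must sum to 1")
        if self.mu_alpha.shape != (N_SECTORS,) or self.mu_beta.shape != (N_SECTORS,):
            raise ConfigError("sector parameter arrays must have length 12")
        if self.visit_interval <= 0 or self.followup_mean <= 0:
            raise ConfigError("visit interval and follow-up must be positive")
        if self.min_visits > self.visits_mean + 4 * self.visits_sd:
            raise ConfigError(
                "min_visits is unreachable given the visit-count distribution"
            )

    @property
    def interaction_name(self) -> str | None:
        if self.interaction is None:
            return None
        return f"{self.interaction[0]}_x_{self.interaction[1]}"

    @property
    def effect_columns(self) -> list[str]:
        """Main-effect covariate columns needed to apply δ and γ."""
        names = []
        for d in (self.delta, self.gamma):
            for k in d:
                if k != self.interaction_name and k not in names:
                    names.append(k)
        if self.interaction is not None:
            for comp in self.interaction:
                if comp not in names:
                    names.append(comp)
        return names


@dataclass
class GroundTruth:
    """Every latent quantity behind a generated cohort."""

    config: GeneratorConfig
    delta: dict
    gamma: dict
    subject_intercepts: np.ndarray     # a_i
    subject_slopes: np.ndarray         # b_i
    sector_intercepts: np.ndarray      # ã_ij, (N, 12)
    sector_slopes: np.ndarray          # b̃_ij
    residual_sd: np.ndarray            # σ_ij, (N, 12)
    outlier_rows: np.ndarray           # row indices into measurements
    scenario_slopes: dict              # realized-sample scenario functionals
    smap_means: dict
    smap_sds: dict

    def to_json(self, path=None) -> str:
        payload = {
            "delta": self.delta,
            "gamma": self.gamma,
            "subject_intercepts": self.subject_intercepts.tolist(),
            "subject_slopes": self.subject_slopes.tolist(),
            "sector_intercepts": self.sector_intercepts.tolist(),
            "sector_slopes": self.sector_slopes.tolist(),
            "residual_sd": self.residual_sd.tolist(),
            "outlier_rows": self.outlier_rows.tolist(),
            "scenario_slopes": {str(k): v for k, v in self.scenario_slopes.items()},
            "smap_means": self.smap_means,
            "smap_sds": self.smap_sds,
            "config": _config_payload(self.config),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _config_payload(config: GeneratorConfig) -> dict:
    payload = asdict(config)
    payload["mu_alpha"] = config.mu_alpha.tolist()
    payload["mu_beta"] = config.mu_beta.tolist()
    if payload["interaction"] is not None:
        payload["interaction"] = list(payload["interaction"])
    return payload


def config_to_yaml(config: GeneratorConfig, path=None) -> str:
    import yaml

    text = yaml.safe_dump(_config_payload(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> GeneratorConfig:
    import yaml

    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(source)
    return GeneratorConfig(**payload)


# ---------------------------------------------------------------------------
# Generation


def _bivariate(rng, n, sd1, sd2, rho):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = sd1 * z1
    y = sd2 * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    return x, y


def _draw_covariates(config: GeneratorConfig, rng) -> pd.DataFrame:
    n = config.n_subjects
    mg = config.marginals
    cov = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})
    # DBP and IOP share a Gaussian copula so the BP–IOP correlation knob is
    # honoured; both are truncated to positive values.
    r = config.bp_iop_correlation
    z_bp, z_iop = _bivariate(rng, n, 1.0, 1.0, r)
    dbp = mg["dbp"][0] + mg["dbp"][1] * z_bp
    iop = mg["iop"][0] + mg["iop"][1] * z_iop
    for _ in range(100):
        bad = (iop <= 0) | (dbp <= 0)
        if not bad.any():
            break
        zb, zi = _bivariate(rng, int(bad.sum()), 1.0, 1.0, r)
        dbp[bad] = mg["dbp"][0] + mg["dbp"][1] * zb
        iop[bad] = mg["iop"][0] + mg["iop"][1] * zi
    sbp = mg["sbp"][0] + mg["sbp"][1] * rng.standard_normal(n)
    for _ in range(100):
        bad = sbp <= dbp
        if not bad.any():
            break
        sbp[bad] = mg["sbp"][0] + mg["sbp"][1] * rng.standard_normal(int(bad.sum()))
    cov["dbp_mmhg"] = dbp
    cov["sbp_mmhg"] = sbp
    cov["iop_mmhg"] = iop
    cov["age_years"] = mg["age"][0] + mg["age"][1] * rng.standard_normal(n)
    cov["cct_um"] = mg["cct"][0] + mg["cct"][1] * rng.standard_normal(n)
    cov["axial_length_mm"] = (
        mg["axial_length"][0] + mg["axial_length"][1] * rng.standard_normal(n)
    )
    cov["cs12"] = mg["cs12"][0] + mg["cs12"][1] * rng.standard_normal(n)
    cov["md_db"] = mg["md"][0] + mg["md"][1] * rng.standard_normal(n)
    cov["sex"] = np.where(rng.random(n) < config.p_female, "female", "male")
    cov["ethnicity"] = rng.choice(
        ["White", "Black", "Hispanic", "Asian"], size=n,
        p=list(config.ethnicity_probs),
    )
    for col, p in (
        ("diabetes", config.p_diabetes),
        ("hypertension", config.p_hypertension),
        ("bp_medication", config.p_bp_medication),
        ("beta_blocker", config.p_beta_blocker),
    ):
        cov[col] = (rng.random(n) < p).astype(int)
    return cov


def _visit_schedule(config: GeneratorConfig, rng) -> list[np.ndarray]:
    out = []
    for _ in range(config.n_subjects):
        fup = max(2.0, config.followup_mean
                  + config.followup_sd * rng.standard_normal())
        # semiannual grid with the final scan exactly at end of follow-up
        grid = np.arange(0.0, fup - config.visit_interval / 2,
                         config.visit_interval)
        grid = np.append(grid, fup)
        target = int(np.clip(
            round(config.visits_mean + config.visits_sd * rng.standard_normal()),
            config.min_visits, len(grid),
        ))
        if target < len(grid):
            interior = rng.choice(
                np.arange(1, len(grid) - 1), size=target - 2, replace=False,
            )
            keep = np.sort(np.concatenate([[0, len(grid) - 1], interior]))
            t = grid[keep]
        else:
            t = grid
        jitter = config.visit_jitter_sd * rng.standard_normal(len(t))
        jitter[0] = 0.0  # baseline defines t = 0
        t = np.maximum(t + jitter, 0.0)
        t = np.sort(t)
        # keep visits strictly separated so (subject, t, sector) stays unique
        for k in range(1, len(t)):
            if t[k] - t[k - 1] < 1e-3:
                t[k] = t[k - 1] + 1e-3
        out.append(t)
    return out


def _planted_z(config: GeneratorConfig, covariates: pd.DataFrame):
    """Realized standardized design and the planted effect vectors."""
    encoded = encode_covariates(covariates)
    columns = []
    for col in config.effect_columns:
        if encoded[col].std(ddof=1) > 0:
            columns.append(col)
        elif config.delta.get(col, 0.0) or config.gamma.get(col, 0.0):
            raise ConfigError(
                f"covariate {col!r} has a planted effect but zero variance "
                "in this draw; increase n_subjects"
            )
        # constant null-effect columns contribute nothing and are dropped
    smap, z = standardize_covariates(encoded, columns,
                                     interaction=config.interaction)
    zd = np.zeros(len(z))
    zg = np.zeros(len(z))
    for name, val in config.delta.items():
        if name in z.columns:
            zd += val * z[name].to_numpy()
    for name, val in config.gamma.items():
        if name in z.columns:
            zg += val * z[name].to_numpy()
    return smap, z, zd, zg


def _realized_scenario_slopes(config, smap, encoded, percentiles=(10, 90)):
    if config.interaction is None:
        return {}
    bp_var = config.interaction[0]
    out = {}
    for bp_q in percentiles:
        for iop_q in percentiles:
            row = {}
            for col in smap.columns:
                vals = encoded[col].to_numpy(float)
                if set(np.unique(vals)) <= {0.0, 1.0}:
                    row[col] = 0.0
                else:
                    row[col] = float(vals.mean())
            row[bp_var] = float(np.quantile(encoded[bp_var], bp_q / 100.0))
            row["iop"] = float(np.quantile(encoded["iop"], iop_q / 100.0))
            zrow = smap.transform(pd.DataFrame([row]))
            slope = float(config.mu_beta.mean())
            for name, val in config.gamma.items():
                if name in zrow.columns:
                    slope += val * float(zrow[name].iloc[0])
            out[(bp_q, iop_q)] = slope
    return out


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int = 0) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort and its ground truth.

    The returned cohort is loader-valid: one eye per subject, baseline at
    t = 0, a global row per visit equal (exactly) to the mean of the 12
    sector rows, planted outliers and low-quality scans included but not
    yet flagged.
    """
    config = GeneratorConfig() if config is None else config
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    covariates = _draw_covariates(config, rng)
    schedules = _visit_schedule(config, rng)
    smap, z, zd, zg = _planted_z(config, covariates)

    a, b = _bivariate(rng, n, config.sd_subject_intercept,
                      config.sd_subject_slope, config.rho_subject)
    at = np.empty((n, N_SECTORS))
    bt = np.empty((n, N_SECTORS))
    for j in range(N_SECTORS):
        at[:, j], bt[:, j] = _bivariate(
            rng, n, config.tau_alpha, config.tau_beta, config.rho_sector
        )
    with np.errstate(invalid="ignore"):
        sigma = np.exp(
            config.m_log_sigma
            + config.s_log_sigma * rng.standard_normal((n, N_SECTORS))
        )
    sigma = np.nan_to_num(sigma, nan=0.0)

    eyes = rng.choice(["OD", "OS"], size=n)
    rows = []
    sector_row_index = []  # (row position in frame) for sector rows only
    for i in range(n):
        t = schedules[i]
        alpha_i = config.mu_alpha + zd[i] + a[i] + at[i]       # (12,)
        beta_i = config.mu_beta + zg[i] + b[i] + bt[i]
        n_vis = len(t)
        qual = np.where(
            rng.random(n_vis) < config.low_quality_frac,
            rng.uniform(5.0, 14.9, size=n_vis),
            np.clip(config.quality_mean
                    + config.quality_sd * rng.standard_normal(n_vis),
                    15.01, None),
        )
        noise = rng.standard_normal((n_vis, N_SECTORS)) * sigma[i]
        y = alpha_i[None, :] + np.outer(t, beta_i) + noise
        for k in range(n_vis):
            for j in range(N_SECTORS):
                sector_row_index.append(len(rows))
                rows.append((covariates["subject_id"].iloc[i], eyes[i],
                             float(t[k]), j + 1, y[k, j], float(qual[k])))
            rows.append((covariates["subject_id"].iloc[i], eyes[i],
                         float(t[k]), GLOBAL_SECTOR, np.nan, float(qual[k])))
    meas = pd.DataFrame(
        rows,
        columns=["subject_id", "eye", "t_years", "sector", "thickness_um",
                 "quality"],
    )

    # plant outliers on sector rows, then fill global rows as exact means
    sector_rows = np.asarray(sector_row_index)
    n_out = int(round(config.outlier_frac * len(sector_rows)))
    outlier_rows = np.sort(rng.choice(sector_rows, size=n_out, replace=False)) \
        if n_out else np.empty(0, dtype=int)
    if n_out:
        signs = rng.choice([-1.0, 1.0], size=n_out)
        mags = rng.uniform(config.outlier_min_sd, config.outlier_max_sd, n_out)
        subj_of = meas.loc[outlier_rows, "subject_id"].map(
            {s: i for i, s in enumerate(covariates["subject_id"])}
        ).to_numpy()
        sect_of = meas.loc[outlier_rows, "sector"].to_numpy(int) - 1
        spike_sd = np.maximum(sigma[subj_of, sect_of], 1e-12)
        meas.loc[outlier_rows, "thickness_um"] += signs * mags * spike_sd
    # clip to positive thickness *before* filling global rows, so the
    # global value stays the exact mean of the stored sector values
    meas["thickness_um"] = meas["thickness_um"].clip(lower=1e-6)
    glob = meas["sector"] == GLOBAL_SECTOR
    sector_means = (
        meas[~glob].groupby(["subject_id", "t_years"])["thickness_um"].mean()
    )
    keys = list(zip(meas.loc[glob, "subject_id"], meas.loc[glob, "t_years"]))
    meas.loc[glob, "thickness_um"] = sector_means.loc[keys].to_numpy()
    meas["excluded"] = False
    meas["exclusion_reason"] = "none"

    cohort = Cohort(meas, covariates, metadata={"generator_seed": seed})
    cohort.validate()
    truth = GroundTruth(
        config=config,
        delta=dict(config.delta),
        gamma=dict(config.gamma),
        subject_intercepts=a,
        subject_slopes=b,
        sector_intercepts=at,
        sector_slopes=bt,
        residual_sd=sigma,
        outlier_rows=outlier_rows,
        scenario_slopes=_realized_scenario_slopes(
            config, smap, encode_covariates(covariates)
        ),
        smap_means=dict(smap.means),
        smap_sds=dict(smap.sds),
    )
    return cohort, truth


def true_scenario_slopes(config: GeneratorConfig,
                         percentiles=(10, 90)) -> dict:
    """Closed-form scenario rates of change under the generating marginals.

    Evaluates the planted slope functional at normal-quantile BP/IOP values
    (other numerics at their population means, indicators at reference),
    ignoring truncation — an analytic approximation to the realized-sample
    functional stored in :class:`GroundTruth`.
    """
    if config.interaction is None:
        return {(p, q): float(config.mu_beta.mean())
                for p in percentiles for q in percentiles}
    bp_var, _ = config.interaction
    r = config.bp_iop_correlation
    ref_z = {
        "sex_female": config.p_female,
        "diabetes": config.p_diabetes,
        "hypertension": config.p_hypertension,
        "bp_medication": config.p_bp_medication,
        "beta_blocker": config.p_beta_blocker,
        "eth_black": config.ethnicity_probs[1],
        "eth_hispanic": config.ethnicity_probs[2],
        "eth_asian": config.ethnicity_probs[3],
    }
    out = {}
    for bp_q in percentiles:
        for iop_q in percentiles:
            z_bp = float(stats.norm.ppf(bp_q / 100.0))
            z_iop = float(stats.norm.ppf(iop_q / 100.0))
            z_int = (z_bp * z_iop - r) / np.sqrt(1.0 + r * r)
            slope = float(config.mu_beta.mean())
            for name, val in config.gamma.items():
                if name == config.interaction_name:
                    slope += val * z_int
                elif name == bp_var:
                    slope += val * z_bp
                elif name == "iop":
                    slope += val * z_iop
                elif name in ref_z:
                    p = ref_z[name]
                    slope += val * (-p / np.sqrt(p * (1.0 - p)))
                # other numeric covariates sit at their mean: z = 0
            out[(bp_q, iop_q)] = slope
    return out
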
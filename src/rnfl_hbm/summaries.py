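"""Posterior reporting: raw-scale coefficients, Bayesian P values, scenarios.

Coefficients are sampled on the standardized covariate scale; before
reporting they are algebraically re-expressed per draw in raw covariate
units, expanding the re-standardized interaction product so that the raw
main-effect coefficients absorb its centering terms and the raw-scale
linear predictor is pointwise identical to the standardized one.

Significance uses one-sided Bayesian P values: the posterior probability
that a coefficient lies on the opposite side of zero from its posterior
mean, significant when P < 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, NamingError, ProvenanceError
from .model import ModelSpec
from .preprocess import StandardizationMap, encode_covariates
from .sampler import PosteriorDraws

#: Binary/indicator covariates reported on the indicator scale and pinned to
#: the reference level (0) in scenarios.
INDICATOR_COVARIATES = (
    "sex_female", "eth_black", "eth_hispanic", "eth_asian",
    "hypertension", "bp_medication", "diabetes", "beta_blocker",
)

#: Multipliers from per-unit raw coefficients to the reporting scale.
REPORTING_SCALES = {
    "age": 10.0,        # per 10 years
    "cct": 10.0,        # per 10 μm
    "dbp": 10.0,        # per 10 mmHg
    "sbp": 10.0,        # per 10 mmHg
    "dbp_x_iop": 10.0,  # per (10 mmHg × mmHg)
    "sbp_x_iop": 10.0,
}

_LABELS = {
    "age": "Age at baseline (/10 yrs)",
    "sex_female": "Female sex",
    "eth_black": "Black",
    "eth_hispanic": "Hispanic",
    "eth_asian": "Asian",
    "hypertension": "Hypertension",
    "bp_medication": "History of blood pressure medication",
    "diabetes": "Diabetes mellitus",
    "cct": "Central corneal thickness (/10 μm)",
    "axial_length": "Axial length (/mm)",
    "cs12": "Contrast sensitivity at 12 cycles per degree",
    "md": "24-2 visual field mean deviation (/dB)",
    "beta_blocker": "β-blocker use",
    "iop": "IOP (/mmHg)",
    "dbp": "DBP (/10 mmHg)",
    "sbp": "SBP (/10 mmHg)",
    "dbp_x_iop": "DBP (/10) × IOP interaction",
    "sbp_x_iop": "SBP (/10) × IOP interaction",
}

#: Report row order (reference level row inserted after sex).
_ROW_ORDER = [
    "age", "sex_female", "__white_ref__", "eth_black", "eth_hispanic",
    "eth_asian", "hypertension", "bp_medication", "diabetes", "cct",
    "axial_length", "cs12", "md", "beta_blocker", "iop", "dbp", "sbp",
    "dbp_x_iop", "sbp_x_iop",
]


# ---------------------------------------------------------------------------
# Back-transformation


def back_transform(
    draws: PosteriorDraws,
    smap: StandardizationMap,
    side: str = "gamma",
    reporting_scales: dict | None = None,
):
    """Re-express standardized coefficient draws in raw covariate units.

    Returns ``(coef, const)``: ``coef`` is a DataFrame of shape
    (total draws × coefficients) on the requested reporting scales and
    ``const`` the per-draw constant offset absorbed by the intercept (raw
    scale), such that for any covariate point
    ``coef_per_unit @ x + const == z(x) @ standardized_coef`` per draw.
    """
    if side not in ("delta", "gamma"):
        raise NamingError(f"side must be 'delta' or 'gamma', got {side!r}")
    names = draws.delta_names if side == "delta" else draws.gamma_names
    std = draws.stacked(side)  # (D, K)
    scales = REPORTING_SCALES if reporting_scales is None else reporting_scales
    inter_name = smap.interaction[2] if smap.interaction else None
    for name in names:
        if name != inter_name and name not in smap.columns:
            raise NamingError(f"coefficient {name!r} not in standardization map")
    D = std.shape[0]
    raw = {name: np.zeros(D) for name in names}
    const = np.zeros(D)
    for k, name in enumerate(names):
        c = std[:, k]
        if name == inter_name:
            a, b, _ = smap.interaction
            sa, sb = smap.sds[a], smap.sds[b]
            ma, mb = smap.means[a], smap.means[b]
            cc = c / (smap.product_sd * sa * sb)
            raw[name] += cc
            if a in raw:
                raw[a] += -cc * mb
            if b in raw:
                raw[b] += -cc * ma
            const += cc * ma * mb - c * smap.product_mean / smap.product_sd
        else:
            raw[name] += c / smap.sds[name]
            const += -c * smap.means[name] / smap.sds[name]
    coef = pd.DataFrame({n: raw[n] * scales.get(n, 1.0) for n in names})
    return coef, const


def bp_decrease_effect(bp_coef: float, interaction_coef: float, iop: float) -> float:
    """Plug-in change in RoC per one reporting unit *lower* BP at fixed IOP.

    With slope coefficients β_BP and β_BP×IOP on the same BP reporting
    scale, a decrease of one BP unit changes the rate of change by
    −(β_BP + β_BP×IOP · IOP); negative values mean faster thinning.
    """
    return -(bp_coef + interaction_coef * iop)


# ---------------------------------------------------------------------------
# Bayesian P values and coefficient summaries


def bayesian_p(coef_draws) -> float:
    """Folded one-sided Bayesian P value.

    The empirical posterior probability that the coefficient lies on the
    opposite side of zero from its posterior mean: Pr(c > 0) when the mean
    is negative, Pr(c < 0) otherwise.  Significance at P < 0.025 is
    equivalent to an unfolded tail below 0.025 or above 0.975.
    """
    c = np.asarray(coef_draws, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("bayesian_p needs at least one draw")
    if c.mean() < 0:
        return float(np.mean(c > 0))
    return float(np.mean(c < 0))


def format_p(p: float, floor: float = 0.001) -> str:
    return f"< {floor}" if p < floor else f"{p:.3f}"


def summarize_coefficients(
    draws: PosteriorDraws,
    smap: StandardizationMap,
    side: str = "gamma",
    reporting_scales: dict | None = None,
) -> pd.DataFrame:
    """Raw-scale posterior mean, SD, equal-tailed 95% CrI and one-sided P
    per covariate coefficient — the rows of the report tables."""
    coef, _ = back_transform(draws, smap, side=side,
                             reporting_scales=reporting_scales)
    rows = []
    for name in coef.columns:
        c = coef[name].to_numpy()
        lo, hi = np.quantile(c, [0.025, 0.975])
        p = bayesian_p(c)
        rows.append({
            "covariate": name,
            "label": _LABELS.get(name, name),
            "mean": float(c.mean()),
            "sd": float(c.std(ddof=1)),
            "cri_lower": float(lo),
            "cri_upper": float(hi),
            "p_value": p,
            "significant": p < 0.025,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hypothetical-subject scenarios


@dataclass
class SlopeScenario:
    """Posterior global rate of change for one hypothetical subject.

    BP and IOP sit at the stated sample percentiles, other numeric
    covariates at sample means, indicators at their reference level (0).
    """

    bp_variable: str
    bp_percentile: float
    iop_percentile: float
    bp_value: float
    iop_value: float
    slope_draws: np.ndarray
    intercept_draws: np.ndarray
    fit_id: str
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = (
                f"{self.bp_variable.upper()} p{self.bp_percentile:g} / "
                f"IOP p{self.iop_percentile:g}"
            )

    @property
    def mean(self) -> float:
        return float(self.slope_draws.mean())

    @property
    def cri(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.slope_draws, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def intercept_mean(self) -> float:
        return float(self.intercept_draws.mean())


def _scenario_covariate_row(encoded, smap, bp_var, bp_value, iop_value):
    row = {}
    for col in smap.columns:
        if col in INDICATOR_COVARIATES:
            row[col] = 0.0
        else:
            row[col] = float(encoded[col].mean())
    row[bp_var] = float(bp_value)
    row["iop"] = float(iop_value)
    return pd.DataFrame([row])


def scenario_slopes(
    draws: PosteriorDraws,
    smap: StandardizationMap,
    spec: ModelSpec,
    covariates: pd.DataFrame,
    bp_percentiles=(10, 90),
    iop_percentiles=(10, 90),
) -> list[SlopeScenario]:
    """Posterior global RoC for each (BP, IOP) percentile combination.

    Per draw, the global rate of change is the mean over sectors of μ_j^β
    plus z(x)ᵀγ at the scenario covariate point; percentiles are type-7
    sample quantiles of the cohort.  The analogous intercept-side
    functional (mean μ_j^α + z(x)ᵀδ) is carried along for fitted lines.
    """
    if spec.interaction is None:
        raise ConfigError("scenario_slopes requires a fitted interaction model")
    bp_var = spec.interaction[0]
    encoded = (
        covariates
        if set(smap.columns) <= set(covariates.columns)
        else encode_covariates(covariates)
    )
    mu_b = draws.stacked("mu_beta").mean(axis=1)   # (D,)
    mu_a = draws.stacked("mu_alpha").mean(axis=1)
    gamma = draws.stacked("gamma")
    delta = draws.stacked("delta") if "delta" in draws.params else None
    out = []
    for bp_q in bp_percentiles:
        for iop_q in iop_percentiles:
            bp_value = float(np.quantile(encoded[bp_var].to_numpy(float),
                                         bp_q / 100.0))
            iop_value = float(np.quantile(encoded["iop"].to_numpy(float),
                                          iop_q / 100.0))
            xrow = _scenario_covariate_row(encoded, smap, bp_var,
                                           bp_value, iop_value)
            z = smap.transform(xrow)
            zg = z[draws.gamma_names].to_numpy(float)[0]
            slope = mu_b + gamma @ zg
            if delta is not None and draws.delta_names:
                zd = z[draws.delta_names].to_numpy(float)[0]
                intercept = mu_a + delta @ zd
            else:
                intercept = mu_a
            out.append(SlopeScenario(
                bp_variable=bp_var,
                bp_percentile=float(bp_q),
                iop_percentile=float(iop_q),
                bp_value=bp_value,
                iop_value=iop_value,
                slope_draws=slope,
                intercept_draws=intercept,
                fit_id=draws.fit_id,
            ))
    return out


def scenario_differences(scenarios: list[SlopeScenario]) -> pd.DataFrame:
    """Pairwise posterior differences of scenario slopes (paired per draw)."""
    if len(scenarios) < 2:
        raise ConfigError("need at least 2 scenarios to difference")
    ids = {s.fit_id for s in scenarios}
    if len(ids) > 1:
        raise ProvenanceError(
            "scenarios come from different fits; differences would pair "
            "unrelated draws"
        )
    rows = []
    for i, s1 in enumerate(scenarios):
        for s2 in scenarios[i + 1:]:
            d = s1.slope_draws - s2.slope_draws
            lo, hi = np.quantile(d, [0.025, 0.975])
            width = float(hi - lo)
            p = 0.5 if np.allclose(d, 0) else bayesian_p(d)
            rows.append({
                "scenario_a": s1.label,
                "scenario_b": s2.label,
                "mean": float(d.mean()),
                "cri_lower": float(lo),
                "cri_upper": float(hi),
                "cri_width": width,
                "p_value": p,
                "significant": p < 0.025 and width > 0,
            })
    return pd.DataFrame(rows)


def fitted_lines(scenarios: list[SlopeScenario], time_grid) -> pd.DataFrame:
    """Plot-ready posterior-mean regression lines over a time grid."""
    t = np.asarray(time_grid, dtype=float)
    rows = []
    for s in scenarios:
        values = s.intercept_mean + s.mean * t
        for ti, vi in zip(t, values):
            rows.append({
                "scenario": s.label,
                "bp_variable": s.bp_variable,
                "bp_value": s.bp_value,
                "iop_value": s.iop_value,
                "t_years": float(ti),
                "rnfl_um": float(vi),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simple statistics and tables


def pearson_correlation(x, y):
    """Pearson r with two-sided t-distribution P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def model_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Arrange coefficient summaries in the canonical report row order.

    Inserts the ethnicity reference-level row (no numbers) when ethnicity
    indicators are present.  Use :func:`render_markdown` /
    ``DataFrame.to_csv`` for output.
    """
    have = set(summary["covariate"])
    rows = []
    for key in _ROW_ORDER:
        if key == "__white_ref__":
            if have & {"eth_black", "eth_hispanic", "eth_asian"}:
                rows.append({
                    "covariate": "eth_white", "label": "White (reference)",
                    "mean": np.nan, "sd": np.nan, "cri_lower": np.nan,
                    "cri_upper": np.nan, "p_value": np.nan,
                    "significant": False,
                })
            continue
        if key in have:
            rows.append(summary[summary["covariate"] == key].iloc[0].to_dict())
    for key in summary["covariate"]:
        if key not in _ROW_ORDER:
            rows.append(summary[summary["covariate"] == key].iloc[0].to_dict())
    return pd.DataFrame(rows).reset_index(drop=True)


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of a model table (Posterior Mean, 95% CrI, P)."""
    lines = [
        "| Variable | Posterior Mean | 95% CrI | P Value |",
        "| --- | --- | --- | --- |",
    ]
    for _, row in table.iterrows():
        if np.isnan(row["mean"]):
            lines.append(f"| {row['label']} |  |  |  |")
            continue
        cri = f"({row['cri_lower']:.3f}, {row['cri_upper']:.3f})"
        lines.append(
            f"| {row['label']} | {row['mean']:.3f} | {cri} "
            f"| {format_p(row['p_value'])} |"
        )
    return "\n".join(lines)
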
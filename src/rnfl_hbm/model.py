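"""Model specification and data assembly for the hierarchical growth model.

The generative model for sector thickness y_ijk of subject i, clock-hour
sector j at time t_ik (years from baseline):

    y_ijk = α_ij + β_ij · t_ik + ε_ijk,            ε_ijk ~ N(0, σ_ij²)
    α_ij  = μ_j^α + z_iᵀ δ + a_i + ã_ij
    β_ij  = μ_j^β + z_iᵀ γ + b_i + b̃_ij
    (a_i, b_i)   ~ N₂(0, Σ₀)                        (subject level)
    (ã_ij, b̃_ij) ~ N₂(0, Σ_j)                       (sector-within-subject)
    log σ_ij ~ N(m_j, s_j²)

Each sector contributes 7 interpretable parameters — μ_j^α, μ_j^β, the
random-effect SDs τ_j^α, τ_j^β, their correlation ρ_j, and the residual
log-SD mean m_j and SD s_j — which are exchangeable across sectors on
transformed scales (identity for μ, log for τ and s, Fisher-z for ρ), each
with an unknown global mean G and SD H.  Standardized covariate
coefficients δ (baseline) and γ (rate of change) carry a shrinkage prior
(Bayesian lasso) by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigError, NamingError
from .preprocess import DesignInputs

#: Transformed-scale families of sector-level parameters sharing a (G, H)
#: global mean/SD pair.
SECTOR_PARAM_FAMILIES = (
    "mu_alpha",       # identity scale, μm
    "mu_beta",        # identity scale, μm/year
    "log_tau_alpha",  # log SD of sector random intercepts
    "log_tau_beta",   # log SD of sector random slopes
    "zrho",           # Fisher-z of intercept–slope correlation
    "m",              # mean of residual log-SD
    "log_s",          # log SD of residual log-SD
)

#: Hyperprior location/scale for each family's global mean G ~ N(g0, v0²).
G_HYPERPRIOR = {
    "mu_alpha": (64.0, 50.0),  # plausible RNFL thickness magnitude
    "mu_beta": (0.0, 10.0),
    "log_tau_alpha": (0.0, 10.0),
    "log_tau_beta": (0.0, 10.0),
    "zrho": (0.0, 10.0),
    "m": (0.0, 10.0),
    "log_s": (0.0, 10.0),
}

#: Half-normal SD for every family's global SD H.
H_HYPERPRIOR_SD = 5.0

#: Half-normal SD for the subject-level random effect SDs in Σ₀.
SIGMA0_SD_PRIOR = 5.0


@dataclass
class MCMCSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.chains < 2:
            raise ConfigError("at least 2 chains are required")
        if self.draws < 1:
            raise ConfigError("at least 1 kept draw is required")


@dataclass
class ModelSpec:
    """Declarative description of which covariates enter the model where.

    ``intercept_covariates`` are main effects on baseline thickness (δ);
    ``slope_covariates`` are covariate-by-time effects on the rate of
    change (γ).  ``interaction`` names a (BP variable, IOP) pair whose
    product term enters *both* lists; the components must already be
    present as main effects in both.
    """

    intercept_covariates: list[str] = field(default_factory=list)
    slope_covariates: list[str] = field(default_factory=list)
    interaction: tuple[str, str] | None = None
    prior: str = "lasso"            # "lasso" | "normal" | "flat"
    prior_scale: float = 10.0       # SD of the diffuse normal prior
    subject_effects: bool = True
    sector_effects: bool = True
    fixed_sigma: float | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCSettings(**self.mcmc)
        if self.interaction is not None:
            self.interaction = tuple(self.interaction)
        self.validate()

    def validate(self) -> None:
        if self.prior not in ("lasso", "normal", "flat"):
            raise ConfigError(f"unknown prior family {self.prior!r}")
        if self.interaction is not None:
            a, b = self.interaction
            for comp in (a, b):
                if comp not in self.intercept_covariates:
                    raise NamingError(
                        f"interaction component {comp!r} must be an intercept "
                        "main effect"
                    )
                if comp not in self.slope_covariates:
                    raise NamingError(
                        f"interaction component {comp!r} must be a slope "
                        "main effect"
                    )
        self.mcmc.validate()

    @property
    def interaction_name(self) -> str | None:
        if self.interaction is None:
            return None
        return f"{self.interaction[0]}_x_{self.interaction[1]}"

    @property
    def delta_names(self) -> list[str]:
        names = list(self.intercept_covariates)
        if self.interaction is not None:
            names.append(self.interaction_name)
        return names

    @property
    def gamma_names(self) -> list[str]:
        names = list(self.slope_covariates)
        if self.interaction is not None:
            names.append(self.interaction_name)
        return names

    @property
    def all_main_covariates(self) -> list[str]:
        seen: list[str] = []
        for name in self.intercept_covariates + self.slope_covariates:
            if name not in seen:
                seen.append(name)
        return seen

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        if payload["interaction"] is not None:
            payload["interaction"] = list(payload["interaction"])
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and "\n" not in source
        ):
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(io.StringIO(str(source)))
        return cls(**payload)


class Model:
    """Compiled model: spec + per-series sufficient statistics.

    Because the mean is linear in time, every Gibbs update only needs the
    per-series statistics (n, Σt, Σt², Σy, Σty, Σy²); iteration cost is
    O(#series), independent of the number of visits.
    """

    def __init__(self, design: DesignInputs, spec: ModelSpec):
        self.design = design
        self.spec = spec
        z_cols = set(design.z.columns)
        for name in spec.delta_names + spec.gamma_names:
            if name not in z_cols:
                raise NamingError(
                    f"spec references covariate {name!r} absent from design"
                )
        self.N = design.n_subjects
        sectors = np.unique(design.series_sector) if design.n_series else np.arange(12)
        #: sector codes present (0-based clock-hour index)
        self.sector_codes = np.asarray(sorted(set(sectors.tolist()) or {0}), dtype=int)
        self.J = len(self.sector_codes)
        code_to_j = {c: j for j, c in enumerate(self.sector_codes)}
        self.S = design.n_series
        self.subj = np.asarray(design.series_subject, dtype=int)
        self.sect = np.asarray(
            [code_to_j[c] for c in design.series_sector], dtype=int
        )
        n = np.array([len(t) for t in design.series_t], dtype=float)
        self.n = n
        self.St = np.array([t.sum() for t in design.series_t])
        self.Stt = np.array([(t * t).sum() for t in design.series_t])
        self.Sy = np.array([y.sum() for y in design.series_y])
        self.Sty = np.array(
            [(t * y).sum() for t, y in zip(design.series_t, design.series_y)]
        )
        self.Syy = np.array([(y * y).sum() for y in design.series_y])
        self.Zd = design.z[spec.delta_names].to_numpy(float) if spec.delta_names \
            else np.zeros((self.N, 0))
        self.Zg = design.z[spec.gamma_names].to_numpy(float) if spec.gamma_names \
            else np.zeros((self.N, 0))
        self.Kd = self.Zd.shape[1]
        self.Kg = self.Zg.shape[1]

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())

    def series_ols(self):
        """Per-series OLS (intercept, slope, residual SD) for initialization."""
        St, Stt, Sy, Sty, n = self.St, self.Stt, self.Sy, self.Sty, self.n
        sxx = Stt - St**2 / n
        sxy = Sty - St * Sy / n
        slope = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-12), 0.0)
        intercept = (Sy - slope * St) / n
        sse = (
            self.Syy
            - 2 * (intercept * Sy + slope * Sty)
            + intercept**2 * n
            + 2 * intercept * slope * St
            + slope**2 * Stt
        )
        dof = np.maximum(n - 2, 1)
        resid_sd = np.sqrt(np.maximum(sse, 0.0) / dof)
        return intercept, slope, resid_sd


def build_model(design: DesignInputs, spec: ModelSpec) -> Model:
    """Validate the spec against the design and compile the model data.

    With empty covariate lists this is the pure growth-curve model with the
    7 interpretable parameters per sector and no regression terms.
    """
    return Model(design, spec)
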
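"""Blocked Gibbs / Metropolis-within-Gibbs sampler for the growth model.

Every location parameter (sector intercepts/slopes, covariate coefficients,
subject- and sector-level random effects) has a Gaussian full conditional
given the variance parameters, so those blocks are drawn exactly.  Variance
and correlation parameters are updated by random-walk Metropolis on
unconstrained scales (log for SDs, Fisher-z for correlations) with step
sizes adapted during warmup only, so post-warmup transition kernels are
fixed and runs are reproducible bit-for-bit given a seed.

The sampler touches the data only through per-series sufficient statistics
(see :class:`~rnfl_hbm.model.Model`), making iteration cost independent of
the number of visits per series.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConvergenceError
from .model import (
    G_HYPERPRIOR,
    H_HYPERPRIOR_SD,
    SECTOR_PARAM_FAMILIES,
    SIGMA0_SD_PRIOR,
    Model,
)

_TINY = 1e-12


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorDraws:
    """MCMC samples with (chain, draw) leading axes.

    ``params`` maps parameter name to an array of shape
    ``(chains, draws, *param_shape)``.  ``fit_id`` is a content hash used to
    verify that summary objects derived from different fits are never
    combined.
    """

    params: dict
    delta_names: list[str]
    gamma_names: list[str]
    sector_codes: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sector_codes = np.asarray(self.sector_codes, dtype=int)
        if "fit_id" not in self.meta:
            h = hashlib.sha1()
            for name in sorted(self.params):
                h.update(name.encode())
                h.update(np.ascontiguousarray(self.params[name]).tobytes())
            self.meta["fit_id"] = h.hexdigest()[:16]

    @property
    def fit_id(self) -> str:
        return self.meta["fit_id"]

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes flattened together."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def coefficient(self, side: str, name: str) -> np.ndarray:
        """Stacked draws of one standardized coefficient (δ or γ)."""
        names = self.delta_names if side == "delta" else self.gamma_names
        idx = names.index(name)
        return self.stacked(side)[:, idx]

    def to_inference_data(self):
        import arviz as az

        dims, coords = {}, {}
        if "mu_alpha" in self.params:
            coords["sector"] = self.sector_codes + 1
            for name in ("mu_alpha", "mu_beta", "tau_alpha", "tau_beta",
                         "rho", "m", "s"):
                if name in self.params:
                    dims[name] = ["sector"]
        if self.delta_names:
            coords["delta_coef"] = list(self.delta_names)
            dims["delta"] = ["delta_coef"]
        if self.gamma_names:
            coords["gamma_coef"] = list(self.gamma_names)
            dims["gamma"] = ["gamma_coef"]
        return az.from_dict(posterior=self.params, coords=coords, dims=dims)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = dict(self.meta)
        meta.update(
            delta_names=self.delta_names,
            gamma_names=self.gamma_names,
            sector_codes=self.sector_codes.tolist(),
        )
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            params=params,
            delta_names=meta.pop("delta_names"),
            gamma_names=meta.pop("gamma_names"),
            sector_codes=np.asarray(meta.pop("sector_codes"), dtype=int),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# Small numerical helpers


def _sample_bivariate(p11, p12, p22, l1, l2, z1, z2):
    """Vectorized draw from N(P⁻¹L, P⁻¹) for 2×2 precision blocks."""
    p11 = np.maximum(p11, _TINY)
    l11 = np.sqrt(p11)
    c21 = p12 / l11
    l22 = np.sqrt(np.maximum(p22 - c21 * c21, _TINY))
    u1 = l1 / l11
    u2 = (l2 - c21 * u1) / l22
    m2 = u2 / l22
    m1 = (u1 - c21 * m2) / l11
    e2 = z1 * 0.0 + z2 / l22
    e1 = (z1 - c21 * e2) / l11
    return m1 + e1, m2 + e2


def _binorm_loglik(saa, sab, sbb, n, log_sa, log_sb, rho):
    """Zero-mean bivariate normal log likelihood from sufficient stats."""
    sa2 = np.exp(2.0 * log_sa)
    sb2 = np.exp(2.0 * log_sb)
    omr = np.maximum(1.0 - rho * rho, _TINY)  # Fisher-z can saturate tanh
    q = saa / sa2 - 2.0 * rho * sab / np.exp(log_sa + log_sb) + sbb / sb2
    return -n * (log_sa + log_sb + 0.5 * np.log(omr)) - q / (2.0 * omr)


def _norm_logpdf(x, m, sd):
    return -0.5 * ((x - m) / sd) ** 2 - np.log(sd)


class _StepSizes:
    """Per-group RW-Metropolis step sizes with warmup-only adaptation."""

    TARGET = 0.44
    TARGET3 = 0.30

    def __init__(self):
        self.steps = {
            "sigma": 0.4, "s": 0.5, "sector_cov": 0.15,
            "sigma0": 0.15, "H": 0.5, "lam": 0.5,
            "rescale_a": 0.1, "rescale_b": 0.3,
            "rescale0_a": 0.05, "rescale0_b": 0.2, "hyper": 0.2,
        }

    def adapt(self, key, acc_rate, iteration, target=None):
        target = target if target is not None else self.TARGET
        kappa = 1.0 / np.sqrt(iteration + 1.0)
        self.steps[key] *= float(np.exp(kappa * (acc_rate - target)))
        self.steps[key] = float(np.clip(self.steps[key], 1e-3, 5.0))


# ---------------------------------------------------------------------------
# Chain state


class _Chain:
    def __init__(self, model: Model, rng: np.random.Generator):
        self.m = model
        self.rng = rng
        self.steps = _StepSizes()
        spec = model.spec
        J, N, S = model.J, model.N, model.S
        a0, b0, rsd = model.series_ols() if S else (np.zeros(0),) * 3

        self.mu_a = np.zeros(J)
        self.mu_b = np.zeros(J)
        if S:
            for j in range(J):
                sel = model.sect == j
                self.mu_a[j] = a0[sel].mean() if sel.any() else 64.0
                self.mu_b[j] = b0[sel].mean() if sel.any() else 0.0
        else:
            self.mu_a += 64.0
        self.delta = np.zeros(model.Kd)
        self.gamma = np.zeros(model.Kg)
        self.a = np.zeros(N)
        self.b = np.zeros(N)
        self.at = np.zeros(S)
        self.bt = np.zeros(S)
        if spec.fixed_sigma is not None:
            self.log_sigma = np.full(S, np.log(spec.fixed_sigma))
        else:
            self.log_sigma = np.log(np.clip(rsd, 0.5, None)) if S else np.zeros(S)
        self.mlog = np.array(
            [self.log_sigma[model.sect == j].mean() if (model.sect == j).any()
             else 0.7 for j in range(J)]
        )
        self.log_s = np.full(J, np.log(0.3))
        self.log_tau_a = np.full(J, np.log(3.0))
        self.log_tau_b = np.full(J, np.log(0.3))
        self.zrho = np.zeros(J)
        self.log_sd0a = np.log(8.0)
        self.log_sd0b = np.log(0.3)
        self.zrho0 = 0.0
        self.G = {f: 0.0 for f in SECTOR_PARAM_FAMILIES}
        self.H = {f: 1.0 for f in SECTOR_PARAM_FAMILIES}
        self.G["mu_alpha"] = float(self.mu_a.mean())
        self.G["mu_beta"] = float(self.mu_b.mean())
        self.G["m"] = float(self.mlog.mean())
        self.G["log_s"] = float(self.log_s.mean())
        self.G["log_tau_alpha"] = float(self.log_tau_a.mean())
        self.G["log_tau_beta"] = float(self.log_tau_b.mean())
        self.omega_d = np.ones(model.Kd)
        self.omega_g = np.ones(model.Kg)
        self.lam_d = 1.0
        self.lam_g = 1.0
        # overdispersed starting points across chains
        jit = rng.standard_normal
        self.mu_a += 0.5 * jit(J)
        self.mu_b += 0.1 * jit(J)
        self.delta += 0.1 * jit(model.Kd)
        self.gamma += 0.05 * jit(model.Kg)
        if spec.fixed_sigma is None:
            self.log_sigma += 0.05 * jit(S)

    # -- predictor pieces ---------------------------------------------------

    def _zd(self):
        return self.m.Zd @ self.delta if self.m.Kd else np.zeros(self.m.N)

    def _zg(self):
        return self.m.Zg @ self.gamma if self.m.Kg else np.zeros(self.m.N)

    def _alpha_beta(self, zd=None, zg=None):
        m = self.m
        zd = self._zd() if zd is None else zd
        zg = self._zg() if zg is None else zg
        alpha = self.mu_a[m.sect] + zd[m.subj] + self.a[m.subj] + self.at
        beta = self.mu_b[m.sect] + zg[m.subj] + self.b[m.subj] + self.bt
        return alpha, beta

    def _coef_prior_precision(self):
        spec = self.m.spec
        if spec.prior == "flat":
            return np.zeros(self.m.Kd), np.zeros(self.m.Kg)
        if spec.prior == "normal":
            p = 1.0 / spec.prior_scale**2
            return np.full(self.m.Kd, p), np.full(self.m.Kg, p)
        return 1.0 / np.maximum(self.omega_d, _TINY), \
            1.0 / np.maximum(self.omega_g, _TINY)

    # -- Gaussian blocks ----------------------------------------------------

    def update_mu(self, w):
        m, J = self.m, self.m.J
        zd, zg = self._zd(), self._zg()
        A = zd[m.subj] + self.a[m.subj] + self.at
        B = zg[m.subj] + self.b[m.subj] + self.bt
        p11 = np.bincount(m.sect, w * m.n, minlength=J)
        p12 = np.bincount(m.sect, w * m.St, minlength=J)
        p22 = np.bincount(m.sect, w * m.Stt, minlength=J)
        l1 = np.bincount(m.sect, w * (m.Sy - A * m.n - B * m.St), minlength=J)
        l2 = np.bincount(m.sect, w * (m.Sty - A * m.St - B * m.Stt), minlength=J)
        if self.hierarchical:
            pa, ma = 1.0 / self.H["mu_alpha"] ** 2, self.G["mu_alpha"]
            pb, mb = 1.0 / self.H["mu_beta"] ** 2, self.G["mu_beta"]
        else:
            g0a, v0a = G_HYPERPRIOR["mu_alpha"]
            g0b, v0b = G_HYPERPRIOR["mu_beta"]
            pa, ma = 1.0 / v0a**2, g0a
            pb, mb = 1.0 / v0b**2, g0b
        self.mu_a, self.mu_b = _sample_bivariate(
            p11 + pa, p12, p22 + pb,
            l1 + pa * ma, l2 + pb * mb,
            self.rng.standard_normal(J), self.rng.standard_normal(J),
        )

    def update_coefficients(self, w):
        m = self.m
        K = m.Kd + m.Kg
        if K == 0:
            return
        A = self.mu_a[m.sect] + self.a[m.subj] + self.at
        B = self.mu_b[m.sect] + self.b[m.subj] + self.bt
        N = m.N
        cn = np.bincount(m.subj, w * m.n, minlength=N)
        ct = np.bincount(m.subj, w * m.St, minlength=N)
        ctt = np.bincount(m.subj, w * m.Stt, minlength=N)
        ra = np.bincount(m.subj, w * (m.Sy - A * m.n - B * m.St), minlength=N)
        rb = np.bincount(m.subj, w * (m.Sty - A * m.St - B * m.Stt), minlength=N)
        P = np.zeros((K, K))
        L = np.zeros(K)
        Kd = m.Kd
        if Kd:
            P[:Kd, :Kd] = (m.Zd * cn[:, None]).T @ m.Zd
            L[:Kd] = m.Zd.T @ ra
        if m.Kg:
            P[Kd:, Kd:] = (m.Zg * ctt[:, None]).T @ m.Zg
            L[Kd:] = m.Zg.T @ rb
        if Kd and m.Kg:
            P[:Kd, Kd:] = (m.Zd * ct[:, None]).T @ m.Zg
            P[Kd:, :Kd] = P[:Kd, Kd:].T
        pd, pg = self._coef_prior_precision()
        P[np.arange(K), np.arange(K)] += np.concatenate([pd, pg]) + _TINY
        C = np.linalg.cholesky(P)
        mean = np.linalg.solve(C.T, np.linalg.solve(C, L))
        draw = mean + np.linalg.solve(C.T, self.rng.standard_normal(K))
        self.delta = draw[:Kd]
        self.gamma = draw[Kd:]

    def update_subject_effects(self, w):
        m, N = self.m, self.m.N
        zd, zg = self._zd(), self._zg()
        A = self.mu_a[m.sect] + zd[m.subj] + self.at
        B = self.mu_b[m.sect] + zg[m.subj] + self.bt
        p11 = np.bincount(m.subj, w * m.n, minlength=N)
        p12 = np.bincount(m.subj, w * m.St, minlength=N)
        p22 = np.bincount(m.subj, w * m.Stt, minlength=N)
        l1 = np.bincount(m.subj, w * (m.Sy - A * m.n - B * m.St), minlength=N)
        l2 = np.bincount(m.subj, w * (m.Sty - A * m.St - B * m.Stt), minlength=N)
        sa2 = np.maximum(np.exp(2 * self.log_sd0a), _TINY)
        sb2 = np.maximum(np.exp(2 * self.log_sd0b), _TINY)
        rho0 = np.tanh(self.zrho0)
        omr = np.maximum(1.0 - rho0 * rho0, _TINY)
        q11 = 1.0 / (sa2 * omr)
        q22 = 1.0 / (sb2 * omr)
        q12 = -rho0 / (np.sqrt(sa2 * sb2) * omr)
        self.a, self.b = _sample_bivariate(
            p11 + q11, p12 + q12, p22 + q22, l1, l2,
            self.rng.standard_normal(N), self.rng.standard_normal(N),
        )

    def update_sector_effects(self, w):
        m, S = self.m, self.m.S
        if S == 0:
            return
        zd, zg = self._zd(), self._zg()
        A = self.mu_a[m.sect] + zd[m.subj] + self.a[m.subj]
        B = self.mu_b[m.sect] + zg[m.subj] + self.b[m.subj]
        ta2 = np.maximum(np.exp(2 * self.log_tau_a), _TINY)[m.sect]
        tb2 = np.maximum(np.exp(2 * self.log_tau_b), _TINY)[m.sect]
        rho = np.tanh(self.zrho)[m.sect]
        omr = np.maximum(1.0 - rho * rho, _TINY)
        q11 = 1.0 / (ta2 * omr)
        q22 = 1.0 / (tb2 * omr)
        q12 = -rho / (np.sqrt(ta2 * tb2) * omr)
        self.at, self.bt = _sample_bivariate(
            w * m.n + q11, w * m.St + q12, w * m.Stt + q22,
            w * (m.Sy - A * m.n - B * m.St),
            w * (m.Sty - A * m.St - B * m.Stt),
            self.rng.standard_normal(S), self.rng.standard_normal(S),
        )

    # -- interweaving (ASIS) moves ------------------------------------------
    #
    # Coefficients and population means are strongly correlated a posteriori
    # with the random effects they share a sum with; plain alternation mixes
    # slowly.  After the Gaussian blocks we re-draw them in the *centered*
    # parameterization: holding the sums (e.g. z_iᵀδ + a_i) fixed — which
    # leaves the likelihood untouched — the coefficient conditional involves
    # only the random-effect prior, and the random effects are recentered
    # afterwards.  Both moves are exact Gibbs steps.

    def _mu_prior(self):
        if self.hierarchical:
            return (1.0 / self.H["mu_alpha"] ** 2, self.G["mu_alpha"],
                    1.0 / self.H["mu_beta"] ** 2, self.G["mu_beta"])
        g0a, v0a = G_HYPERPRIOR["mu_alpha"]
        g0b, v0b = G_HYPERPRIOR["mu_beta"]
        return 1.0 / v0a**2, g0a, 1.0 / v0b**2, g0b

    def interweave_coefficients(self):
        m = self.m
        K = m.Kd + m.Kg
        if K == 0 or not m.spec.subject_effects:
            return
        c = self._zd() + self.a
        d = self._zg() + self.b
        sa = max(np.exp(self.log_sd0a), 1e-8)
        sb = max(np.exp(self.log_sd0b), 1e-8)
        rho0 = np.tanh(self.zrho0)
        omr = max(1.0 - rho0 * rho0, _TINY)
        q11 = 1.0 / (sa * sa * omr)
        q22 = 1.0 / (sb * sb * omr)
        q12 = -rho0 / (sa * sb * omr)
        Kd = m.Kd
        P = np.zeros((K, K))
        L = np.zeros(K)
        if Kd:
            P[:Kd, :Kd] = q11 * (m.Zd.T @ m.Zd)
            L[:Kd] = m.Zd.T @ (q11 * c + q12 * d)
        if m.Kg:
            P[Kd:, Kd:] = q22 * (m.Zg.T @ m.Zg)
            L[Kd:] = m.Zg.T @ (q12 * c + q22 * d)
        if Kd and m.Kg:
            P[:Kd, Kd:] = q12 * (m.Zd.T @ m.Zg)
            P[Kd:, :Kd] = P[:Kd, Kd:].T
        pd, pg = self._coef_prior_precision()
        P[np.arange(K), np.arange(K)] += np.concatenate([pd, pg]) + _TINY
        C = np.linalg.cholesky(P)
        mean = np.linalg.solve(C.T, np.linalg.solve(C, L))
        draw = mean + np.linalg.solve(C.T, self.rng.standard_normal(K))
        self.delta = draw[:Kd]
        self.gamma = draw[Kd:]
        self.a = c - self._zd()
        self.b = d - self._zg()

    def interweave_mu(self):
        m, J = self.m, self.m.J
        if not m.spec.sector_effects or m.S == 0:
            return
        ca = self.mu_a[m.sect] + self.at
        cb = self.mu_b[m.sect] + self.bt
        nj = np.bincount(m.sect, minlength=J).astype(float)
        sca = np.bincount(m.sect, ca, minlength=J)
        scb = np.bincount(m.sect, cb, minlength=J)
        ta = np.maximum(np.exp(self.log_tau_a), 1e-8)
        tb = np.maximum(np.exp(self.log_tau_b), 1e-8)
        rho = np.tanh(self.zrho)
        omr = np.maximum(1.0 - rho * rho, _TINY)
        q11 = 1.0 / (ta * ta * omr)
        q22 = 1.0 / (tb * tb * omr)
        q12 = -rho / (ta * tb * omr)
        pa, ma, pb, mb = self._mu_prior()
        self.mu_a, self.mu_b = _sample_bivariate(
            nj * q11 + pa, nj * q12, nj * q22 + pb,
            q11 * sca + q12 * scb + pa * ma,
            q12 * sca + q22 * scb + pb * mb,
            self.rng.standard_normal(J), self.rng.standard_normal(J),
        )
        self.at = ca - self.mu_a[m.sect]
        self.bt = cb - self.mu_b[m.sect]

    # Weakly identified random-effect SDs suffer the usual funnel in the
    # centered parameterization, so they also get a non-centered step:
    # holding ξ = effect/SD fixed, a random-walk Metropolis move on the
    # log-SDs rescales the effects and is accepted on the likelihood ratio
    # plus the SD prior — the ξ prior does not involve the SDs.

    def _series_loglik(self, at, bt, w):
        m = self.m
        zd, zg = self._zd(), self._zg()
        alpha = self.mu_a[m.sect] + zd[m.subj] + self.a[m.subj] + at
        beta = self.mu_b[m.sect] + zg[m.subj] + self.b[m.subj] + bt
        sse = (m.Syy - 2.0 * (alpha * m.Sy + beta * m.Sty)
               + alpha**2 * m.n + 2.0 * alpha * beta * m.St
               + beta**2 * m.Stt)
        return -0.5 * w * sse

    def _tau_prior(self, fam):
        if self.hierarchical:
            return self.G[fam], self.H[fam]
        return G_HYPERPRIOR[fam]

    def rescale_sector_scales(self, w):
        """Two non-centered moves per sector: (i) rescale the intercept
        effects with log τ^α; (ii) jointly move (log τ^β, Fisher-z ρ)
        rescaling the slope effects.  With the whitening ordered intercept
        first, move (ii) leaves the intercept effects untouched."""
        m, J = self.m, self.m.J
        if m.S == 0:
            return 1.0, 1.0
        base = self._series_loglik(self.at, self.bt, w)
        # (i) τ^α move
        da = self.steps.steps["rescale_a"] * self.rng.standard_normal(J)
        at2 = self.at * np.exp(da)[m.sect]
        dll = np.bincount(m.sect, self._series_loglik(at2, self.bt, w) - base,
                          minlength=J)
        ga, ha = self._tau_prior("log_tau_alpha")
        dprior = (_norm_logpdf(self.log_tau_a + da, ga, ha)
                  - _norm_logpdf(self.log_tau_a, ga, ha))
        acc_a = np.log(self.rng.random(J)) < dll + dprior
        self.log_tau_a = self.log_tau_a + np.where(acc_a, da, 0.0)
        self.at = np.where(acc_a[m.sect], at2, self.at)
        # (ii) joint (τ^β, ρ) move holding the whitened effects fixed
        base = self._series_loglik(self.at, self.bt, w)
        step = self.steps.steps["rescale_b"]
        db = step * self.rng.standard_normal(J)
        dz = step * self.rng.standard_normal(J)
        tau_a = np.exp(self.log_tau_a)
        tau_b = np.exp(self.log_tau_b)
        rho = np.tanh(self.zrho)
        tau_b2 = np.exp(self.log_tau_b + db)
        rho2 = np.tanh(self.zrho + dz)
        xi1 = self.at / np.maximum(tau_a, 1e-8)[m.sect]
        xi2 = (self.bt / np.maximum(tau_b, 1e-8)[m.sect] - rho[m.sect] * xi1) \
            / np.sqrt(np.maximum(1.0 - rho[m.sect] ** 2, _TINY))
        bt2 = tau_b2[m.sect] * (
            rho2[m.sect] * xi1 + np.sqrt(1.0 - rho2[m.sect] ** 2) * xi2
        )
        dll = np.bincount(m.sect, self._series_loglik(self.at, bt2, w) - base,
                          minlength=J)
        gb, hb = self._tau_prior("log_tau_beta")
        gz, hz = self._tau_prior("zrho")
        dprior = (_norm_logpdf(self.log_tau_b + db, gb, hb)
                  - _norm_logpdf(self.log_tau_b, gb, hb)
                  + _norm_logpdf(self.zrho + dz, gz, hz)
                  - _norm_logpdf(self.zrho, gz, hz))
        acc_b = np.log(self.rng.random(J)) < dll + dprior
        self.log_tau_b = self.log_tau_b + np.where(acc_b, db, 0.0)
        self.zrho = self.zrho + np.where(acc_b, dz, 0.0)
        self.bt = np.where(acc_b[m.sect], bt2, self.bt)
        return float(acc_a.mean()), float(acc_b.mean())

    def rescale_subject_scales(self, w):
        """Same two non-centered moves for the subject-level covariance."""
        if self.m.S == 0:
            return 1.0, 1.0

        def half_normal_term(ls):
            return -0.5 * np.exp(2 * ls) / SIGMA0_SD_PRIOR**2 + ls

        base = self._series_loglik(self.at, self.bt, w).sum()
        da = self.steps.steps["rescale0_a"] * self.rng.standard_normal()
        a2 = self.a * np.exp(da)
        cur_a = self.a
        self.a = a2
        dll = self._series_loglik(self.at, self.bt, w).sum() - base
        self.a = cur_a
        acc_a = 0.0
        if np.log(self.rng.random()) < dll + half_normal_term(self.log_sd0a + da) \
                - half_normal_term(self.log_sd0a):
            self.log_sd0a += da
            self.a = a2
            acc_a = 1.0
        base = self._series_loglik(self.at, self.bt, w).sum()
        step = self.steps.steps["rescale0_b"]
        db = step * self.rng.standard_normal()
        dz = step * self.rng.standard_normal()
        sd_a = np.exp(self.log_sd0a)
        sd_b = np.exp(self.log_sd0b)
        rho0 = np.tanh(self.zrho0)
        sd_b2 = np.exp(self.log_sd0b + db)
        rho2 = np.tanh(self.zrho0 + dz)
        xi1 = self.a / max(sd_a, 1e-8)
        xi2 = (self.b / max(sd_b, 1e-8) - rho0 * xi1) \
            / np.sqrt(max(1.0 - rho0**2, _TINY))
        b2 = sd_b2 * (rho2 * xi1 + np.sqrt(1.0 - rho2**2) * xi2)
        cur_b = self.b
        self.b = b2
        dll = self._series_loglik(self.at, self.bt, w).sum() - base
        self.b = cur_b
        dprior = (half_normal_term(self.log_sd0b + db)
                  - half_normal_term(self.log_sd0b)
                  + np.log1p(-rho2**2) - np.log1p(-rho0**2))
        acc_b = 0.0
        if np.log(self.rng.random()) < dll + dprior:
            self.log_sd0b += db
            self.zrho0 += dz
            self.b = b2
            acc_b = 1.0
        return acc_a, acc_b

    # -- Metropolis blocks --------------------------------------------------

    def _sse(self):
        m = self.m
        alpha, beta = self._alpha_beta()
        return (
            m.Syy
            - 2.0 * (alpha * m.Sy + beta * m.Sty)
            + alpha**2 * m.n
            + 2.0 * alpha * beta * m.St
            + beta**2 * m.Stt
        )

    def update_sigma(self):
        m = self.m
        if m.S == 0:
            return 1.0
        sse = np.maximum(self._sse(), 0.0)
        th = self.log_sigma
        prop = th + self.steps.steps["sigma"] * self.rng.standard_normal(m.S)
        s_j = np.exp(self.log_s)[m.sect]
        m_j = self.mlog[m.sect]

        def logp(t):
            return (-m.n * t - 0.5 * sse * np.exp(-2.0 * t)
                    + _norm_logpdf(t, m_j, s_j))

        accept = np.log(self.rng.random(m.S)) < logp(prop) - logp(th)
        self.log_sigma = np.where(accept, prop, th)
        return float(accept.mean())

    def update_residual_hierarchy(self):
        m, J = self.m, self.m.J
        nj = np.bincount(m.sect, minlength=J).astype(float)
        sum_ls = np.bincount(m.sect, self.log_sigma, minlength=J)
        s2 = np.exp(2.0 * self.log_s)
        if self.hierarchical:
            g_m, h_m = self.G["m"], self.H["m"]
            g_s, h_s = self.G["log_s"], self.H["log_s"]
        else:
            g_m, h_m = G_HYPERPRIOR["m"]
            g_s, h_s = G_HYPERPRIOR["log_s"]
        prec = nj / s2 + 1.0 / h_m**2
        mean = (sum_ls / s2 + g_m / h_m**2) / prec
        self.mlog = mean + self.rng.standard_normal(J) / np.sqrt(prec)
        # scale of the residual log-SDs, random walk on log s_j
        ss = np.bincount(m.sect, (self.log_sigma - self.mlog[m.sect]) ** 2,
                         minlength=J)
        th = self.log_s
        prop = th + self.steps.steps["s"] * self.rng.standard_normal(J)

        def logp(t):
            return -nj * t - 0.5 * ss * np.exp(-2.0 * t) + _norm_logpdf(t, g_s, h_s)

        accept = np.log(self.rng.random(J)) < logp(prop) - logp(th)
        self.log_s = np.where(accept, prop, th)
        return float(accept.mean())

    def update_sector_covariances(self):
        m, J = self.m, self.m.J
        nj = np.bincount(m.sect, minlength=J).astype(float)
        saa = np.bincount(m.sect, self.at**2, minlength=J)
        sbb = np.bincount(m.sect, self.bt**2, minlength=J)
        sab = np.bincount(m.sect, self.at * self.bt, minlength=J)
        if self.hierarchical:
            pri = [(self.G["log_tau_alpha"], self.H["log_tau_alpha"]),
                   (self.G["log_tau_beta"], self.H["log_tau_beta"]),
                   (self.G["zrho"], self.H["zrho"])]
        else:
            pri = [G_HYPERPRIOR["log_tau_alpha"], G_HYPERPRIOR["log_tau_beta"],
                   G_HYPERPRIOR["zrho"]]
        step = self.steps.steps["sector_cov"]
        cur = np.stack([self.log_tau_a, self.log_tau_b, self.zrho])
        prop = cur + step * self.rng.standard_normal((3, J))

        def logp(v):
            lta, ltb, zr = v
            rho = np.tanh(zr)
            ll = _binorm_loglik(saa, sab, sbb, nj, lta, ltb, rho)
            for x, (g, h) in zip(v, pri):
                ll = ll + _norm_logpdf(x, g, h)
            return ll

        accept = np.log(self.rng.random(J)) < logp(prop) - logp(cur)
        self.log_tau_a = np.where(accept, prop[0], cur[0])
        self.log_tau_b = np.where(accept, prop[1], cur[1])
        self.zrho = np.where(accept, prop[2], cur[2])
        return float(accept.mean())

    def update_sigma0(self):
        N = self.m.N
        saa = float(self.a @ self.a)
        sbb = float(self.b @ self.b)
        sab = float(self.a @ self.b)
        step = self.steps.steps["sigma0"]
        cur = np.array([self.log_sd0a, self.log_sd0b, self.zrho0])
        prop = cur + step * self.rng.standard_normal(3)

        def logp(v):
            lsa, lsb, zr = v
            rho = np.tanh(zr)
            ll = _binorm_loglik(saa, sab, sbb, float(N), lsa, lsb, rho)
            # half-normal priors on SDs (+ log-scale Jacobian), uniform on ρ
            # (+ Fisher-z Jacobian)
            for ls in (lsa, lsb):
                ll += -0.5 * np.exp(2 * ls) / SIGMA0_SD_PRIOR**2 + ls
            ll += np.log1p(-rho * rho)
            return ll

        if np.log(self.rng.random()) < logp(prop) - logp(cur):
            self.log_sd0a, self.log_sd0b, self.zrho0 = prop
            return 1.0
        return 0.0

    def _family_values(self, fam):
        return {
            "mu_alpha": self.mu_a, "mu_beta": self.mu_b,
            "log_tau_alpha": self.log_tau_a, "log_tau_beta": self.log_tau_b,
            "zrho": self.zrho, "m": self.mlog, "log_s": self.log_s,
        }[fam]

    def update_hyperparameters(self, families):
        J = self.m.J
        acc = []
        for fam in families:
            v = self._family_values(fam)
            g0, v0 = G_HYPERPRIOR[fam]
            H = self.H[fam]
            prec = J / H**2 + 1.0 / v0**2
            mean = (v.sum() / H**2 + g0 / v0**2) / prec
            self.G[fam] = float(mean + self.rng.standard_normal() / np.sqrt(prec))
            ss = float(((v - self.G[fam]) ** 2).sum())
            th = np.log(H)
            prop = th + self.steps.steps["H"] * self.rng.standard_normal()

            def logp(t):
                return (-J * t - 0.5 * ss * np.exp(-2.0 * t)
                        - 0.5 * np.exp(2 * t) / H_HYPERPRIOR_SD**2 + t)

            if np.log(self.rng.random()) < logp(prop) - logp(th):
                self.H[fam] = float(np.exp(prop))
                acc.append(1.0)
            else:
                acc.append(0.0)
        return float(np.mean(acc)) if acc else 1.0

    def hyper_family_move(self, fam, w):
        """Ensemble move for one sector-parameter family.

        Proposes a joint shift/rescale of (G, H, v_1..v_J) that keeps the
        standardized residuals (v_j − G)/H fixed, and propagates the value
        change into the states the family governs (random effects or
        residual SDs).  With residuals preserved, the family prior terms and
        the transform Jacobian cancel exactly, leaving the data likelihood
        ratio and the (G, H) hyperpriors.  This is what lets a family whose
        across-sector spread is small move as a block instead of being
        pinned to a collapsed H.
        """
        m = self.m
        v = self._family_values(fam)
        G, H = self.G[fam], self.H[fam]
        step = self.steps.steps["hyper"]
        dG = step * self.rng.standard_normal()
        dh = step * self.rng.standard_normal()
        G2 = G + dG
        H2 = H * np.exp(dh)
        v2 = G2 + np.exp(dh) * (v - G)
        dv = v2 - v
        dvs = dv[m.sect]
        at2 = bt2 = lsig2 = None
        if fam == "mu_alpha":
            dll = (self._series_loglik(self.at + dvs, self.bt, w)
                   - self._series_loglik(self.at, self.bt, w)).sum()
        elif fam == "mu_beta":
            dll = (self._series_loglik(self.at, self.bt + dvs, w)
                   - self._series_loglik(self.at, self.bt, w)).sum()
        elif fam == "log_tau_alpha":
            at2 = self.at * np.exp(dvs)
            dll = (self._series_loglik(at2, self.bt, w)
                   - self._series_loglik(self.at, self.bt, w)).sum()
        elif fam == "log_tau_beta":
            bt2 = self.bt * np.exp(dvs)
            dll = (self._series_loglik(self.at, bt2, w)
                   - self._series_loglik(self.at, self.bt, w)).sum()
        elif fam == "zrho":
            tau_a = np.exp(self.log_tau_a)[m.sect]
            tau_b = np.exp(self.log_tau_b)[m.sect]
            rho = np.tanh(v)[m.sect]
            rho2 = np.tanh(v2)[m.sect]
            xi1 = self.at / np.maximum(tau_a, 1e-8)
            xi2 = (self.bt / np.maximum(tau_b, 1e-8) - rho * xi1) \
                / np.sqrt(np.maximum(1.0 - rho**2, _TINY))
            bt2 = tau_b * (rho2 * xi1 + np.sqrt(1.0 - rho2**2) * xi2)
            dll = (self._series_loglik(self.at, bt2, w)
                   - self._series_loglik(self.at, self.bt, w)).sum()
        elif fam in ("m", "log_s"):
            sse = np.maximum(self._sse(), 0.0)
            if fam == "m":
                lsig2 = self.log_sigma + dvs
            else:
                mj = self.mlog[m.sect]
                lsig2 = mj + np.exp(dvs) * (self.log_sigma - mj)
            dll = float(
                (-m.n * lsig2 - 0.5 * sse * np.exp(-2.0 * lsig2)).sum()
                - (-m.n * self.log_sigma
                   - 0.5 * sse * np.exp(-2.0 * self.log_sigma)).sum()
            )
        else:  # pragma: no cover - unknown family
            return 0.0
        g0, v0 = G_HYPERPRIOR[fam]
        dprior = (
            _norm_logpdf(G2, g0, v0) - _norm_logpdf(G, g0, v0)
            - 0.5 * (H2**2 - H**2) / H_HYPERPRIOR_SD**2
            + np.log(H2) - np.log(H)
        )
        if np.log(self.rng.random()) < dll + dprior:
            self.G[fam] = float(G2)
            self.H[fam] = float(H2)
            setattr(self, {
                "mu_alpha": "mu_a", "mu_beta": "mu_b",
                "log_tau_alpha": "log_tau_a", "log_tau_beta": "log_tau_b",
                "zrho": "zrho", "m": "mlog", "log_s": "log_s",
            }[fam], v2)
            if at2 is not None:
                self.at = at2
            if bt2 is not None:
                self.bt = bt2
            if lsig2 is not None:
                self.log_sigma = lsig2
            return 1.0
        return 0.0

    def update_lasso(self):
        acc = []
        for coef, which in ((self.delta, "d"), (self.gamma, "g")):
            K = coef.size
            if K == 0:
                continue
            lam = self.lam_d if which == "d" else self.lam_g
            mean = np.minimum(lam / np.maximum(np.abs(coef), 1e-8), 1e8)
            eta = self.rng.wald(mean, lam**2)
            omega = 1.0 / np.maximum(eta, _TINY)
            som = float(omega.sum())
            th = np.log(lam)
            prop = th + self.steps.steps["lam"] * self.rng.standard_normal()

            def logp(t):
                lm2 = np.exp(2.0 * t)
                # Exp(λ²/2) likelihood for the K mixture variances,
                # half-Cauchy(0,1) on the scale (self-reciprocal), log-Jacobian
                return 2.0 * K * t - 0.5 * lm2 * som - np.log1p(lm2) + t

            if np.log(self.rng.random()) < logp(prop) - logp(th):
                lam = float(np.exp(prop))
                acc.append(1.0)
            else:
                acc.append(0.0)
            if which == "d":
                self.omega_d, self.lam_d = omega, lam
            else:
                self.omega_g, self.lam_g = omega, lam
        return float(np.mean(acc)) if acc else 1.0

    # -- one full sweep -----------------------------------------------------

    @property
    def hierarchical(self) -> bool:
        return self.m.J >= 2

    def sweep(self, iteration, adapt):
        spec = self.m.spec
        w = np.exp(-2.0 * self.log_sigma)
        self.update_mu(w)
        self.update_coefficients(w)
        if spec.subject_effects:
            self.update_subject_effects(w)
        if spec.sector_effects:
            self.update_sector_effects(w)
        self.interweave_coefficients()
        self.interweave_mu()
        if spec.sector_effects:
            acc = self.update_sector_covariances()
            if adapt:
                self.steps.adapt("sector_cov", acc, iteration,
                                 _StepSizes.TARGET3)
            acc_a, acc_b = self.rescale_sector_scales(w)
            if adapt:
                self.steps.adapt("rescale_a", acc_a, iteration)
                self.steps.adapt("rescale_b", acc_b, iteration,
                                 _StepSizes.TARGET3)
        if spec.fixed_sigma is None:
            acc = self.update_sigma()
            if adapt:
                self.steps.adapt("sigma", acc, iteration)
            acc = self.update_residual_hierarchy()
            if adapt:
                self.steps.adapt("s", acc, iteration)
        if spec.subject_effects:
            acc = self.update_sigma0()
            if adapt:
                self.steps.adapt("sigma0", acc, iteration, _StepSizes.TARGET3)
            acc_a, acc_b = self.rescale_subject_scales(w)
            if adapt:
                self.steps.adapt("rescale0_a", acc_a, iteration)
                self.steps.adapt("rescale0_b", acc_b, iteration,
                                 _StepSizes.TARGET3)
        if self.hierarchical:
            families = ["mu_alpha", "mu_beta"]
            if spec.sector_effects:
                families += ["log_tau_alpha", "log_tau_beta", "zrho"]
            if spec.fixed_sigma is None:
                families += ["m", "log_s"]
            acc = self.update_hyperparameters(families)
            if adapt:
                self.steps.adapt("H", acc, iteration)
            acc = float(np.mean([
                self.hyper_family_move(fam, w) for fam in families
            ]))
            if adapt:
                self.steps.adapt("hyper", acc, iteration, _StepSizes.TARGET3)
        if spec.prior == "lasso":
            acc = self.update_lasso()
            if adapt:
                self.steps.adapt("lam", acc, iteration)

    def snapshot(self):
        out = {
            "mu_alpha": self.mu_a.copy(),
            "mu_beta": self.mu_b.copy(),
        }
        spec = self.m.spec
        if self.m.Kd:
            out["delta"] = self.delta.copy()
        if self.m.Kg:
            out["gamma"] = self.gamma.copy()
        if spec.sector_effects:
            out["tau_alpha"] = np.exp(self.log_tau_a)
            out["tau_beta"] = np.exp(self.log_tau_b)
            out["rho"] = np.tanh(self.zrho)
        if spec.fixed_sigma is None:
            out["m"] = self.mlog.copy()
            out["s"] = np.exp(self.log_s)
        if spec.subject_effects:
            out["sigma0_sd_a"] = np.exp(self.log_sd0a)
            out["sigma0_sd_b"] = np.exp(self.log_sd0b)
            out["sigma0_rho"] = np.tanh(self.zrho0)
        if self.hierarchical:
            for fam in SECTOR_PARAM_FAMILIES:
                out[f"G_{fam}"] = self.G[fam]
                out[f"H_{fam}"] = self.H[fam]
        if spec.prior == "lasso":
            if self.m.Kd:
                out["lambda_delta"] = self.lam_d
            if self.m.Kg:
                out["lambda_gamma"] = self.lam_g
        return out


# ---------------------------------------------------------------------------
# Public entry point


def sample_posterior(
    model: Model,
    chains: int | None = None,
    warmup: int | None = None,
    draws: int | None = None,
    seed: int | None = None,
    check: bool = False,
    rhat_max: float = 1.1,
    ess_min: float = 100.0,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return posterior draws.

    MCMC settings default to the model spec's.  Runs are reproducible: the
    same (model, settings, seed) give bit-identical draws.  With
    ``check=True`` the draws are screened by
    :func:`~rnfl_hbm.diagnostics.check_convergence` and a
    :class:`~rnfl_hbm.errors.ConvergenceError` carrying the diagnostic
    table is raised on failure.
    """
    mc = model.spec.mcmc
    chains = mc.chains if chains is None else chains
    warmup = mc.warmup if warmup is None else warmup
    draws = mc.draws if draws is None else draws
    seed = mc.seed if seed is None else seed

    stores: dict[str, np.ndarray] | None = None
    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        chain = _Chain(model, rng)
        for it in range(warmup):
            chain.sweep(it, adapt=True)
        for d in range(draws):
            chain.sweep(warmup + d, adapt=False)
            snap = chain.snapshot()
            if stores is None:
                stores = {
                    k: np.empty((chains, draws) + np.shape(v))
                    for k, v in snap.items()
                }
            for k, v in snap.items():
                stores[k][c, d] = v

    posterior = PosteriorDraws(
        params=stores,
        delta_names=model.spec.delta_names,
        gamma_names=model.spec.gamma_names,
        sector_codes=model.sector_codes,
        meta={"seed": seed, "chains": chains, "warmup": warmup, "draws": draws},
    )
    if check:
        from .diagnostics import check_convergence

        report = check_convergence(posterior, rhat_max=rhat_max, ess_min=ess_min)
        if not report["passed"]:
            raise ConvergenceError(
                "MCMC did not converge "
                f"(max R-hat {report['max_rhat']:.3f}, "
                f"min ESS {report['min_ess']:.0f})",
                report=report,
            )
    return posterior
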
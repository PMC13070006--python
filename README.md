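# rnfl-hbm

Bayesian hierarchical longitudinal modelling of retinal nerve fiber layer
(RNFL) thinning in glaucoma.

Glaucoma progression is tracked by the rate of change (RoC, μm/year) of
peripapillary RNFL thickness on OCT. Pooling the 12 clock-hour sectors of
each eye in one hierarchical model makes the global RoC estimate — and the
baseline covariates that predict it, notably the interaction between blood
pressure (BP) and intraocular pressure (IOP) — far better identified than
per-eye regression. This package provides that analysis as a reusable,
tested pipeline for biostatisticians and glaucoma researchers: data model
and CSV I/O, preprocessing (sector averaging, quality and eligibility
filters, outlier removal), the hierarchical model with its own Gibbs
sampler, posterior reporting (raw-scale coefficient tables, one-sided
Bayesian P values, hypothetical-subject scenarios), and a synthetic-cohort
generator with known ground truth, since the clinical data behind the
published analysis are not public.

## The model

For subject i, sector j = 1..12 at time t (years since baseline):

    y_ijt = α_ij + β_ij·t + ε_ijt,              ε_ijt ~ N(0, σ_ij²)
    α_ij  = μ_j^α + z_iᵀδ + a_i + ã_ij          baseline thickness
    β_ij  = μ_j^β + z_iᵀγ + b_i + b̃_ij          rate of change
    (a_i, b_i) ~ N₂(0, Σ₀),  (ã_ij, b̃_ij) ~ N₂(0, Σ_j),  log σ_ij ~ N(m_j, s_j²)

z_i holds the standardized baseline covariates (age, sex, ethnicity, BP,
IOP, corneal thickness, axial length, contrast sensitivity, visual-field
MD, comorbidities, medication) plus a re-standardized BP×IOP product term
entering both δ and γ. Sector-level parameters are exchangeable across
sectors on transformed scales with unknown global means and SDs;
coefficients carry a Bayesian-lasso shrinkage prior. Sampling is a blocked
Gibbs / Metropolis-within-Gibbs scheme with interweaving and non-centered
moves (see `docs/methods.md`); a full 110-eye fit takes seconds.

## Worked example

```python
import rnfl_hbm as rh

cohort, truth = rh.generate_cohort(rh.GeneratorConfig(), seed=7)
cohort = rh.detect_outliers(rh.filter_eligibility(rh.filter_quality(cohort)))

covs = ["age", "sex_female", "diabetes", "cs12", "md", "iop", "dbp"]
design = rh.build_design(cohort, covs, interaction=("dbp", "iop"))
spec = rh.ModelSpec(intercept_covariates=covs, slope_covariates=covs,
                    interaction=("dbp", "iop"),
                    mcmc={"chains": 2, "warmup": 500, "draws": 500})
draws = rh.sample_posterior(rh.build_model(design, spec), seed=7)

table = rh.model_table(rh.summarize_coefficients(draws, design.smap))
scen = rh.scenario_slopes(draws, design.smap, spec, cohort.covariates)
```

The coefficient table reports the effect of each covariate on the global
RoC, back-transformed to raw units (this run prints, among others):

```
                         label   mean  cri_lower  cri_upper  p_value
                   IOP (/mmHg) -0.867     -1.009     -0.722    0.000
                DBP (/10 mmHg) -1.243     -1.440     -1.032    0.000
   DBP (/10) × IOP interaction  0.097      0.080      0.114    0.000
```

A negative mean is faster thinning per unit increase; the positive
interaction means low BP is harmful mainly when IOP is high. The scenario
slopes make that concrete — the posterior global RoC for hypothetical
subjects at the 10th/90th sample percentiles of DBP and IOP (other numeric
covariates at sample means, indicators at reference):

```
DBP p10 / IOP p90: -1.036 μm/year (95% CrI -1.201, -0.842)
DBP p90 / IOP p10: -0.420 μm/year (95% CrI -0.557, -0.286)
DBP p90 / IOP p90: -0.233 μm/year (95% CrI -0.410, -0.061)
DBP p10 / IOP p10:  0.810 μm/year (95% CrI  0.663,  0.949)
```

The low-BP/high-IOP combination thins fastest, recovering the interaction
planted by the generator (standardized magnitude 0.3, here on a synthetic
cohort, so the numbers differ from any clinical values).

The same pipeline runs from a shell:

```
rnfl-hbm all --out run --seed 7 --bp dbp
rnfl-hbm simulate --out cohort --seed 7
rnfl-hbm fit cohort/measurements.csv cohort/covariates.csv --out fit --bp dbp
rnfl-hbm report fit
```

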
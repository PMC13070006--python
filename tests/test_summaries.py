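"""Back-transformation, Bayesian P values, scenarios, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnfl_hbm import ModelSpec
from rnfl_hbm.errors import ConfigError, ProvenanceError
from rnfl_hbm.preprocess import StandardizationMap, standardize_covariates
from rnfl_hbm.sampler import PosteriorDraws
from rnfl_hbm.summaries import (
    back_transform,
    bayesian_p,
    bp_decrease_effect,
    fitted_lines,
    format_p,
    model_table,
    pearson_correlation,
    render_markdown,
    scenario_differences,
    scenario_slopes,
    summarize_coefficients,
)


def _fake_draws(gamma, delta=None, mu_beta=-0.3, mu_alpha=62.0, n=400,
                gamma_names=None, delta_names=None, seed=0, spread=0.02):
    """PosteriorDraws with Gaussian draws around given coefficient values."""
    rng = np.random.default_rng(seed)
    gamma = np.asarray(gamma, dtype=float)
    delta = gamma.copy() if delta is None else np.asarray(delta, dtype=float)
    K = gamma.size
    gamma_names = gamma_names or [f"g{i}" for i in range(K)]
    delta_names = delta_names or gamma_names
    params = {
        "mu_alpha": mu_alpha + spread * rng.standard_normal((2, n, 12)),
        "mu_beta": mu_beta + spread * rng.standard_normal((2, n, 12)),
        "gamma": gamma + spread * rng.standard_normal((2, n, K)),
        "delta": delta + spread * rng.standard_normal((2, n, K)),
    }
    return PosteriorDraws(params=params, delta_names=list(delta_names),
                          gamma_names=list(gamma_names),
                          sector_codes=np.arange(12))


class TestBackTransform:
    def test_identity_map(self):
        draws = _fake_draws([0.5], gamma_names=["x"])
        smap = StandardizationMap(columns=["x"], means={"x": 0.0},
                                  sds={"x": 1.0})
        coef, const = back_transform(draws, smap, reporting_scales={})
        np.testing.assert_allclose(
            coef["x"].to_numpy(), draws.stacked("gamma")[:, 0]
        )
        np.testing.assert_allclose(const, 0.0)

    def test_scaling_by_sd(self):
        draws = _fake_draws([0.5], gamma_names=["x"])
        smap = StandardizationMap(columns=["x"], means={"x": 3.0},
                                  sds={"x": 2.0})
        coef, _ = back_transform(draws, smap, reporting_scales={})
        np.testing.assert_allclose(
            coef["x"].to_numpy(), draws.stacked("gamma")[:, 0] / 2.0
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_predictor_equivalence_with_interaction(self, seed):
        """Raw-scale and standardized-scale linear predictors agree at
        random covariate points, per draw, to 1e-9."""
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame({
            "dbp": rng.normal(82, 10, size=60),
            "iop": rng.normal(12.6, 4, size=60),
            "md": rng.normal(-8, 5, size=60),
        })
        smap, z = standardize_covariates(raw, ["dbp", "iop", "md"],
                                         interaction=("dbp", "iop"))
        names = ["dbp", "iop", "md", "dbp_x_iop"]
        draws = _fake_draws(rng.normal(size=4), gamma_names=names, n=40)
        coef, const = back_transform(draws, smap, reporting_scales={})
        pts = pd.DataFrame({
            "dbp": rng.normal(82, 12, size=100),
            "iop": rng.normal(12, 5, size=100),
            "md": rng.normal(-9, 6, size=100),
        })
        zpts = smap.transform(pts)
        std_pred = zpts[names].to_numpy() @ draws.stacked("gamma").T
        raw_x = pts.copy()
        raw_x["dbp_x_iop"] = pts["dbp"] * pts["iop"]
        raw_pred = raw_x[names].to_numpy() @ coef.to_numpy().T + const
        np.testing.assert_allclose(raw_pred, std_pred, atol=1e-9)

    def test_reporting_scale_applied(self):
        draws = _fake_draws([1.0], gamma_names=["dbp"])
        smap = StandardizationMap(columns=["dbp"], means={"dbp": 80.0},
                                  sds={"dbp": 10.0})
        per_unit, _ = back_transform(draws, smap, reporting_scales={})
        per_ten, _ = back_transform(draws, smap)  # default /10 mmHg
        np.testing.assert_allclose(
            per_ten["dbp"].to_numpy(), 10.0 * per_unit["dbp"].to_numpy()
        )


class TestBayesianP:
    def test_all_positive(self):
        assert bayesian_p(np.ones(100)) == 0.0

    def test_symmetric_is_half(self):
        draws = np.concatenate([np.ones(500), -np.ones(500), [1e-9]])
        assert abs(bayesian_p(draws) - 0.5) < 1e-3

    def test_normal_tail(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(1.0, 1.0, size=100_000)
        from scipy.stats import norm

        assert abs(bayesian_p(draws) - norm.cdf(-1.0)) < 0.004

    def test_equals_tail_fraction_exactly_and_order_invariant(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.3, 1.0, size=997)
        p = bayesian_p(draws)
        assert p == np.mean(draws < 0)
        assert bayesian_p(draws[::-1]) == p

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bayesian_p([])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_p_in_unit_interval(self, values):
        p = bayesian_p(np.asarray(values))
        assert 0.0 <= p <= 1.0


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        # t = r·sqrt(2/(1−r²)); with 2 df the CDF is closed-form and p = 0.4
        assert p == pytest.approx(0.4, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


def _scenario_setup(gamma, seed=0, n_draws=300):
    rng = np.random.default_rng(seed)
    raw = pd.DataFrame({
        "dbp": rng.normal(82, 10, size=80),
        "iop": rng.normal(12.6, 3.9, size=80),
        "md": rng.normal(-8.8, 6, size=80),
    })
    smap, _ = standardize_covariates(raw, ["dbp", "iop", "md"],
                                     interaction=("dbp", "iop"))
    names = ["dbp", "iop", "md", "dbp_x_iop"]
    spec = ModelSpec(intercept_covariates=["dbp", "iop", "md"],
                     slope_covariates=["dbp", "iop", "md"],
                     interaction=("dbp", "iop"))
    draws = _fake_draws(gamma, gamma_names=names, n=n_draws, seed=seed)
    return draws, smap, spec, raw


class TestScenarios:
    def test_zero_gamma_gives_population_slope(self):
        draws, smap, spec, raw = _scenario_setup([0.0, 0.0, 0.0, 0.0])
        draws.params["gamma"] *= 0.0
        scen = scenario_slopes(draws, smap, spec, raw)
        pop = draws.stacked("mu_beta").mean(axis=1).mean()
        assert len(scen) == 4
        for s in scen:
            assert s.mean == pytest.approx(pop, abs=1e-12)

    def test_median_percentiles_collapse(self):
        draws, smap, spec, raw = _scenario_setup([-0.2, -0.15, -0.1, 0.3])
        scen = scenario_slopes(draws, smap, spec, raw,
                               bp_percentiles=(50,), iop_percentiles=(50,))
        assert len(scen) == 1
        # BP/IOP at their medians ~ the mean-covariate prediction
        row = {c: raw[c].mean() for c in ["dbp", "iop", "md"]}
        row["dbp"] = np.quantile(raw["dbp"], 0.5)
        row["iop"] = np.quantile(raw["iop"], 0.5)
        z = smap.transform(pd.DataFrame([row]))
        expect = (draws.stacked("mu_beta").mean(axis=1)
                  + draws.stacked("gamma")
                  @ z[draws.gamma_names].to_numpy(float)[0]).mean()
        assert scen[0].mean == pytest.approx(expect, abs=1e-12)

    def test_planted_interaction_ordering(self):
        # negative main effects, positive interaction: low BP + high IOP worst
        draws, smap, spec, raw = _scenario_setup([-0.15, -0.2, 0.0, 0.3])
        scen = scenario_slopes(draws, smap, spec, raw)
        worst = min(scen, key=lambda s: s.mean)
        assert worst.bp_percentile == 10.0
        assert worst.iop_percentile == 90.0

    def test_requires_interaction(self):
        draws, smap, _, raw = _scenario_setup([0.0, 0.0, 0.0, 0.0])
        spec = ModelSpec(intercept_covariates=["dbp"], slope_covariates=["dbp"])
        with pytest.raises(ConfigError):
            scenario_slopes(draws, smap, spec, raw)


class TestScenarioDifferences:
    def test_self_difference_zero(self):
        draws, smap, spec, raw = _scenario_setup([-0.15, -0.2, 0.0, 0.3])
        scen = scenario_slopes(draws, smap, spec, raw)
        diff = scenario_differences([scen[0], scen[0]])
        assert diff["mean"].iloc[0] == 0.0
        assert diff["cri_width"].iloc[0] == 0.0
        assert not diff["significant"].iloc[0]

    def test_zero_gamma_nothing_significant(self):
        draws, smap, spec, raw = _scenario_setup([0, 0, 0, 0])
        draws.params["gamma"] *= 0.0
        scen = scenario_slopes(draws, smap, spec, raw)
        diff = scenario_differences(scen)
        assert not diff["significant"].any()

    def test_provenance_enforced(self):
        d1, smap, spec, raw = _scenario_setup([0, 0, 0, 0], seed=1)
        d2, *_ = _scenario_setup([0, 0, 0, 0], seed=2)
        s1 = scenario_slopes(d1, smap, spec, raw)
        s2 = scenario_slopes(d2, smap, spec, raw)
        with pytest.raises(ProvenanceError):
            scenario_differences([s1[0], s2[1]])


class TestFittedLines:
    def test_line_geometry(self):
        draws, smap, spec, raw = _scenario_setup([-0.15, -0.2, 0.0, 0.3])
        scen = scenario_slopes(draws, smap, spec, raw)
        grid = np.array([0.0, 1.0, 4.0])
        lines = fitted_lines(scen, grid)
        one = lines[lines["scenario"] == scen[0].label]
        v0 = one[one["t_years"] == 0.0]["rnfl_um"].iloc[0]
        v4 = one[one["t_years"] == 4.0]["rnfl_um"].iloc[0]
        assert v0 == pytest.approx(scen[0].intercept_mean, abs=1e-12)
        assert v4 == pytest.approx(
            scen[0].intercept_mean + 4 * scen[0].mean, abs=1e-12
        )

    def test_zero_slope_horizontal(self):
        draws, smap, spec, raw = _scenario_setup([0, 0, 0, 0])
        draws.params["gamma"] *= 0.0
        draws.params["mu_beta"] *= 0.0
        scen = scenario_slopes(draws, smap, spec, raw)
        lines = fitted_lines(scen[:1], np.linspace(0, 4, 5))
        assert lines["rnfl_um"].nunique() == 1


class TestModelTable:
    def _summary(self, names, seed=0):
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(
            rng.normal(size=(50, len(names))), columns=names
        )
        # give binaries indicator structure
        for c in names:
            if c.startswith("eth_") or c in ("sex_female", "diabetes",
                                             "hypertension", "bp_medication",
                                             "beta_blocker"):
                raw[c] = (raw[c] > 0).astype(float)
        smap, _ = standardize_covariates(raw, names,
                                         interaction=("dbp", "iop"))
        gamma_names = names + ["dbp_x_iop"]
        draws = _fake_draws(rng.normal(size=len(gamma_names)),
                            gamma_names=gamma_names, n=50)
        return summarize_coefficients(draws, smap)

    def test_full_interaction_model_has_17_rows(self):
        names = ["age", "sex_female", "eth_black", "eth_hispanic",
                 "eth_asian", "hypertension", "bp_medication", "diabetes",
                 "cct", "axial_length", "cs12", "md", "beta_blocker",
                 "iop", "dbp"]
        table = model_table(self._summary(names))
        assert len(table) == 17  # 16 coefficients + White reference row
        assert table["mean"].notna().sum() == 16
        assert table["label"].iloc[2] == "White (reference)"

    def test_univariate_model_single_row(self):
        draws = _fake_draws([0.5], gamma_names=["iop"])
        smap = StandardizationMap(columns=["iop"], means={"iop": 12.0},
                                  sds={"iop": 4.0})
        table = model_table(summarize_coefficients(draws, smap))
        assert len(table) == 1

    def test_csv_roundtrip(self, tmp_path):
        names = ["iop", "dbp", "md"]
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.normal(size=(30, 3)), columns=names)
        smap, _ = standardize_covariates(raw, names, interaction=("dbp", "iop"))
        draws = _fake_draws(rng.normal(size=4),
                            gamma_names=names + ["dbp_x_iop"], n=30)
        table = model_table(summarize_coefficients(draws, smap))
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back["covariate"]) == list(table["covariate"])
        np.testing.assert_allclose(back["mean"], table["mean"])

    def test_markdown_renders(self):
        draws = _fake_draws([0.5], gamma_names=["iop"])
        smap = StandardizationMap(columns=["iop"], means={"iop": 12.0},
                                  sds={"iop": 4.0})
        md = render_markdown(model_table(summarize_coefficients(draws, smap)))
        assert md.startswith("| Variable |")
        assert "IOP" in md


def test_format_p_floor():
    assert format_p(0.0005) == "< 0.001"
    assert format_p(0.2) == "0.200"


def test_bp_decrease_effect_sign_convention():
    # positive interaction: the BP effect flips sign as IOP grows
    low = bp_decrease_effect(-0.5, 0.05, 4.0)
    high = bp_decrease_effect(-0.5, 0.05, 16.0)
    assert low > 0 > high
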
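"""Sector averaging, filters, outlier removal, standardization."""

import numpy as np
import pandas as pd
import pytest

from rnfl_hbm import GeneratorConfig, generate_cohort
from rnfl_hbm.cohort import GLOBAL_SECTOR
from rnfl_hbm.errors import (
    DegenerateCovariateError,
    DimensionError,
    EmptyCohortError,
    NamingError,
)
from rnfl_hbm.preprocess import (
    _studentized_residuals,
    build_design,
    detect_outliers,
    encode_covariates,
    filter_eligibility,
    filter_quality,
    sector_thickness,
    standardize_covariates,
)

from conftest import make_tiny_cohort


class TestSectorThickness:
    def test_constant_profile(self):
        sectors, g = sector_thickness(np.full(768, 60.0))
        np.testing.assert_allclose(sectors, 60.0)
        assert g == 60.0

    def test_index_profile(self):
        sectors, g = sector_thickness(np.arange(768, dtype=float))
        assert sectors[0] == 31.5
        assert sectors[11] == 735.5
        assert g == 383.5

    def test_single_hot_block(self):
        v = np.full(768, 50.0)
        v[128:192] = 100.0  # third block of 64
        sectors, g = sector_thickness(v)
        assert np.sum(sectors == 100.0) == 1
        assert sectors[2] == 100.0
        np.testing.assert_allclose(g, 50.0 + 50.0 / 12.0)

    def test_global_is_mean_of_sectors(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(40, 120, size=768)
        sectors, g = sector_thickness(v)
        np.testing.assert_allclose(sectors.mean(), g, atol=1e-9)

    def test_wrong_length(self):
        with pytest.raises(DimensionError):
            sector_thickness(np.ones(767))


class TestQualityFilter:
    def test_nothing_removed_when_all_good(self, tiny_cohort):
        out = filter_quality(tiny_cohort, 15.0)
        assert not out.measurements["excluded"].any()

    def test_boundary_scan_flagged(self, tiny_cohort):
        meas = tiny_cohort.measurements
        scan = (meas["subject_id"] == "P00") & (meas["t_years"] == 0.5)
        tiny_cohort.measurements.loc[scan, "quality"] = 14.9
        out = filter_quality(tiny_cohort, 15.0)
        flagged = out.measurements["excluded"]
        assert flagged.sum() == 13  # 12 sectors + global of that scan
        assert (out.measurements.loc[flagged, "exclusion_reason"] == "quality").all()

    def test_threshold_is_inclusive(self, tiny_cohort):
        meas = tiny_cohort.measurements
        for t, q in ((0.0, 14.0), (0.5, 15.0), (1.0, 16.0)):
            sel = (meas["subject_id"] == "P00") & (meas["t_years"] == t)
            meas.loc[sel, "quality"] = q
        out = filter_quality(tiny_cohort, 15.0)
        excl = out.measurements[out.measurements["excluded"]]
        assert set(excl["t_years"]) == {0.0}


class TestEligibility:
    def test_too_few_scans_removed(self):
        cohort = make_tiny_cohort(n_visits=3)  # 3 scans over 1 year
        with pytest.raises(EmptyCohortError):
            filter_eligibility(cohort, 4, 2.0)

    def test_short_followup_removed(self):
        # 5 scans but compressed into 1.9 years
        cohort = make_tiny_cohort(n_visits=5)
        cohort.measurements["t_years"] *= 1.9 / 2.0
        with pytest.raises(EmptyCohortError):
            filter_eligibility(cohort, 4, 2.0)

    def test_inclusive_bounds_retained(self):
        # exactly 4 scans spanning exactly 2.0 years
        cohort = make_tiny_cohort(n_visits=4)
        cohort.measurements["t_years"] *= 2.0 / 1.5
        out = filter_eligibility(cohort, 4, 2.0)
        assert out.n_subjects == 2

    def test_partial_removal_logged(self):
        cohort = make_tiny_cohort(n_visits=6)
        short = cohort.measurements["subject_id"] == "P01"
        cohort.measurements = cohort.measurements[
            ~(short & (cohort.measurements["t_years"] > 1.0))
        ].reset_index(drop=True)
        out = filter_eligibility(cohort, 4, 2.0)
        assert out.subjects == ["P00"]
        log = out.metadata["filter_log"]["eligibility"]
        assert log["subjects_removed"] == ["P01"]


class TestOutliers:
    def test_linear_series_clean(self, tiny_cohort):
        out = detect_outliers(tiny_cohort, z_threshold=0.0)
        # noise-free linear series have zero residuals everywhere
        assert out.metadata["filter_log"]["outliers"]["records_flagged"] == 0

    def test_planted_spike_flagged(self):
        cohort = make_tiny_cohort(n_visits=8)
        meas = cohort.measurements
        sel = (
            (meas["subject_id"] == "P00") & (meas["sector"] == 3)
        )
        idx = meas.index[sel]
        # add mild noise so the OLS residual variance is nonzero
        rng = np.random.default_rng(1)
        meas.loc[idx, "thickness_um"] += rng.normal(0, 1.0, size=len(idx))
        spike_idx = idx[4]
        meas.loc[spike_idx, "thickness_um"] += 30.0
        out = detect_outliers(cohort, z_threshold=3.0)
        flagged = out.measurements[
            out.measurements["exclusion_reason"] == "outlier"
        ]
        assert spike_idx in set(flagged.index)
        assert (flagged["sector"] == 3).all()

    def test_studentized_residuals_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 4, size=9))
        y = 60 - 0.5 * t + rng.normal(0, 2, size=9)
        ours = _studentized_residuals(t, y)
        model = sm.OLS(y, sm.add_constant(t)).fit()
        theirs = model.get_influence().resid_studentized_external
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_reapplication_flags_nothing_more(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=10), seed=3)
        once = detect_outliers(cohort, z_threshold=4.0, max_iter=3)
        twice = detect_outliers(once, z_threshold=4.0, max_iter=3)
        n1 = once.metadata["filter_log"]["outliers"]["records_flagged"]
        n2 = twice.metadata["filter_log"]["outliers"]["records_flagged"]
        assert n1 >= 0
        assert n2 <= max(1, int(0.1 * max(n1, 1)))  # essentially nothing new

    def test_short_series_skipped(self):
        cohort = make_tiny_cohort(n_visits=2)
        out = detect_outliers(cohort, z_threshold=4.0)
        log = out.metadata["filter_log"]["outliers"]
        assert log["records_flagged"] == 0
        assert len(log["skipped_series"]) == 24  # 2 subjects × 12 sectors

    def test_series_never_below_three_points(self):
        cohort = make_tiny_cohort(n_visits=4)
        meas = cohort.measurements
        sel = (meas["subject_id"] == "P00") & (meas["sector"] == 1)
        idx = meas.index[sel]
        rng = np.random.default_rng(0)
        meas.loc[idx, "thickness_um"] += rng.normal(0, 0.5, size=len(idx))
        meas.loc[idx[1], "thickness_um"] += 50.0
        meas.loc[idx[2], "thickness_um"] -= 50.0
        out = detect_outliers(cohort, z_threshold=1.0, max_iter=5)
        retained = out.retained_measurements()
        n_left = ((retained["subject_id"] == "P00")
                  & (retained["sector"] == 1)).sum()
        assert n_left >= 3


class TestStandardization:
    def test_population_sd_example(self):
        df = pd.DataFrame({"iop": [8.0, 12.0, 16.0]})
        smap, z = standardize_covariates(df, ["iop"], ddof=0)
        np.testing.assert_allclose(
            z["iop"].to_numpy(), [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_idempotent_on_zscores(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=50)
        zed = (raw - raw.mean()) / raw.std(ddof=1)
        df = pd.DataFrame({"x": zed})
        _, z = standardize_covariates(df, ["x"])
        np.testing.assert_allclose(z["x"].to_numpy(), zed, atol=1e-12)

    def test_degenerate_covariate_named(self):
        df = pd.DataFrame({"sex_female": [1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateCovariateError, match="sex_female"):
            standardize_covariates(df, ["sex_female"])

    def test_unknown_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(NamingError, match="nope"):
            standardize_covariates(df, ["nope"])

    def test_roundtrip_and_moments(self, small_synthetic):
        cohort, _ = small_synthetic
        enc = encode_covariates(cohort.covariates)
        cols = ["age", "iop", "dbp", "md", "cs12"]
        smap, z = standardize_covariates(enc, cols, interaction=("dbp", "iop"))
        for col in cols:
            assert abs(z[col].mean()) < 1e-9
            assert abs(z[col].std(ddof=1) - 1.0) < 1e-9
        assert abs(z["dbp_x_iop"].mean()) < 1e-9
        assert abs(z["dbp_x_iop"].std(ddof=1) - 1.0) < 1e-9
        raw = smap.inverse(z)
        for col in cols:
            np.testing.assert_allclose(
                raw[col].to_numpy(), enc[col].to_numpy(), atol=1e-9
            )

    def test_interaction_requires_components(self, small_synthetic):
        cohort, _ = small_synthetic
        enc = encode_covariates(cohort.covariates)
        with pytest.raises(NamingError):
            standardize_covariates(enc, ["age"], interaction=("dbp", "iop"))


class TestBuildDesign:
    def test_series_and_shapes(self, small_synthetic):
        cohort, _ = small_synthetic
        design = build_design(cohort, ["iop", "dbp"], interaction=("dbp", "iop"))
        assert design.z.shape == (cohort.n_subjects, 3)
        assert design.n_series == 12 * cohort.n_subjects
        assert all(len(t) >= 2 for t in design.series_t)
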
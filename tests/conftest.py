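import numpy as np
import pandas as pd
import pytest

from rnfl_hbm import GeneratorConfig, generate_cohort
from rnfl_hbm.cohort import Cohort, GLOBAL_SECTOR


def make_tiny_cohort(n_visits=5, n_subjects=2, slope=-0.5, base=60.0):
    """Hand-built noise-free cohort: linear series, exact global means."""
    rows = []
    cov_rows = []
    for i in range(n_subjects):
        subj = f"P{i:02d}"
        cov_rows.append({
            "subject_id": subj, "age_years": 60.0 + i, "sex": "female",
            "ethnicity": "White", "dbp_mmhg": 80.0 + i, "sbp_mmhg": 130.0,
            "iop_mmhg": 12.0 + i, "cct_um": 540.0, "axial_length_mm": 24.0,
            "cs12": 4.0, "md_db": -8.0, "diabetes": 0, "hypertension": 0,
            "bp_medication": 0, "beta_blocker": 0,
        })
        for k in range(n_visits):
            t = 0.5 * k
            sector_vals = [base + j + i * 5 + slope * t for j in range(12)]
            for j, v in enumerate(sector_vals, start=1):
                rows.append((subj, "OD", t, j, v, 25.0, False, "none"))
            rows.append((subj, "OD", t, GLOBAL_SECTOR,
                         float(np.mean(sector_vals)), 25.0, False, "none"))
    meas = pd.DataFrame(rows, columns=[
        "subject_id", "eye", "t_years", "sector", "thickness_um", "quality",
        "excluded", "exclusion_reason",
    ])
    return Cohort(meas, pd.DataFrame(cov_rows)).validate()


@pytest.fixture
def tiny_cohort():
    return make_tiny_cohort()


@pytest.fixture(scope="session")
def small_synthetic():
    """One small generated cohort shared by read-only tests."""
    cohort, truth = generate_cohort(GeneratorConfig(n_subjects=15), seed=42)
    return cohort, truth
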
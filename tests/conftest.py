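import numpy as np
import pandas as pd
import pytest

from diabclust import default_config, generate_cohort
from diabclust.config import CohortConfig, FeatureDist


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-stratum synthetic cohort with genotypes (shared, read-only)."""
    cfg = default_config(seed=7, n_new_onset=400, n_long_term=600)
    return generate_cohort(cfg, with_genotypes=True)


@pytest.fixture()
def tiny_cohort_df():
    """Hand-built 6-row phenotyped cohort frame (complete, inlier)."""
    return pd.DataFrame({
        "patient_id": [f"T{i}" for i in range(6)],
        "sex": ["male", "female", "male", "female", "male", "female"],
        "age": [60.0, 55.0, 70.0, 48.0, 63.0, 52.0],
        "age_at_onset": [55.0, 50.0, 60.0, 45.0, 58.0, 47.0],
        "duration": [5.0, 5.0, 10.0, 3.0, 5.0, 5.0],
        "bmi": [28.0, 31.0, 27.0, 35.0, 30.0, 29.0],
        "waist": [95.0, 100.0, 92.0, 110.0, 98.0, 96.0],
        "hba1c": [7.5, 8.0, 7.0, 9.0, 7.8, 8.2],
        "fasting_glucose": [8.0, 9.0, 7.5, 10.0, 8.5, 9.2],
        "c_peptide": [0.9, 1.1, 0.8, 1.4, 1.0, 1.2],
        "gada": [1.0, 8.0, 2.0, 1.5, 0.5, 3.0],
        "creatinine": [80.0, 70.0, 95.0, 65.0, 85.0, 75.0],
        "homa2_b": [70.0, 90.0, 60.0, 120.0, 80.0, 95.0],
        "homa2_ir": [2.0, 2.5, 1.8, 3.5, 2.2, 2.6],
        "proliferative_retinopathy": [False] * 6,
        "laser_treatment": [False, True, False, False, False, False],
        "blindness": [False] * 6,
        "documented_nephropathy": [False, False, True, False, False, False],
        "dialysis": [False] * 6,
        "esrd": [False] * 6,
        "mi": [False, False, False, False, True, False],
        "stroke": [False] * 6,
        "peripheral_neuropathy": [True, False, True, False, True, False],
        "insulin_treatment": [False] * 6,
    })


def well_separated_config(seed: int, n_new: int = 600, n_long: int = 600) -> CohortConfig:
    """A config with exaggerated centroid separation for recovery property tests."""
    cfg = default_config(seed=seed, n_new_onset=n_new, n_long_term=n_long)
    for stratum in cfg.strata.values():
        for spec in stratum.clusters.values():
            for dist in spec.features.values():
                dist.sd = max(dist.sd * 0.5, 1e-3)
    return cfg
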
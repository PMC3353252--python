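import numpy as np
import pytest

import riskport as rp
from riskport.synthetic_cohort import CohortGeneratorConfig


@pytest.fixture(scope="session")
def published():
    return rp.load_published_models()


@pytest.fixture(scope="session")
def cohort_2k():
    """Synthetic cohort of 2,000 subjects with its generating model."""
    return rp.generate_cohort(CohortGeneratorConfig(n=2000), seed=42, return_model=True)


@pytest.fixture(scope="session")
def cohort_5k():
    """Larger synthetic cohort (5,000) for recovery-style checks."""
    return rp.generate_cohort(CohortGeneratorConfig(n=5000), seed=7, return_model=True)


@pytest.fixture()
def subject():
    """One complete, eligible subject record."""
    return {
        "id": "S1", "age": 40.0, "sex": "female", "ethnicity": "Chinese",
        "fpg": 5.35, "two_hpg": 5.6, "sbp": 115.0, "hdl": 1.26,
        "triglyceride": 1.3, "bmi": 22.8, "waist": 74.0, "height": 160.0,
        "family_history_t2dm": 0, "physician_dx_baseline": 0,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
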
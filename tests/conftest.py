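import numpy as np
import pytest

from sccbounds.datasets import load_hypertension_cohort, load_lung_cancer_casecontrol


@pytest.fixture(scope="session")
def hypertension_cohort():
    return load_hypertension_cohort()


@pytest.fixture(scope="session")
def hypertension_risks(hypertension_cohort):
    return hypertension_cohort.risk_matrix()


@pytest.fixture(scope="session")
def lung_cancer_table():
    return load_lung_cancer_casecontrol()


def random_risk_matrix(rng, L1, L2, high=0.95):
    """Uniform risks bounded away from 1 (survival stays positive)."""
    return rng.uniform(0.0, high, size=(L1, L2))
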
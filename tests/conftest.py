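import numpy as np
import pytest

from twinsat.simulate import simulate_cohort
from twinsat.truth import CohortDesign, GeneratingTruth, univariate_truth


@pytest.fixture(scope="session")
def balanced_design():
    """Small balanced complete-response design used across tests."""
    return CohortDesign(n_mz_m=100, n_dz_m=100, n_mz_f=100, n_dz_f=100,
                        single_responder_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def bivariate_ae_truth():
    """Bivariate AE truth with correlated genetic and environmental parts."""
    L_A = np.array([[0.7, 0.0], [0.3, 0.5]])
    L_E = np.array([[0.71414284, 0.0], [0.2, 0.78102497]])
    return GeneratingTruth(("X", "Y"), L_A=L_A, L_E=L_E)


@pytest.fixture(scope="session")
def bivariate_cohort(bivariate_ae_truth, balanced_design):
    return simulate_cohort(bivariate_ae_truth, balanced_design)


@pytest.fixture(scope="session")
def univariate_cohort_large():
    """Large univariate AE cohort (a2 = 0.5) for moment checks."""
    truth = univariate_truth(0.5, "LS")
    design = CohortDesign(n_mz_m=4000, n_dz_m=4000, n_mz_f=4000, n_dz_f=4000,
                          single_responder_rate=0.0, seed=7)
    return simulate_cohort(truth, design)
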
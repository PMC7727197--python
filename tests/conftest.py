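import numpy as np
import pytest

from censelect import CovariateDesign, sample_covariates


@pytest.fixture(scope="session")
def block_X():
    """n=500, p=30 with one 5-variable block at |rho_S| = 0.97, rest independent."""
    design = CovariateDesign(p=30, n=500, blocks=((5, 0.97),), seed=11,
                             missing_rate=0.02)
    return sample_covariates(design)


@pytest.fixture(scope="session")
def indep_X():
    """n=400, p=12 independent standardized Gaussian columns."""
    design = CovariateDesign(p=12, n=400, seed=5)
    return sample_covariates(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
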
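import numpy as np
import pytest

import genderpaths as gp


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size cohort with latent truth columns retained."""
    return gp.generate_cohort(gp.GeneratorConfig(seed=1), keep_truth=True)


@pytest.fixture(scope="session")
def analysis_cohort(default_cohort):
    """Default cohort with index / dichotomisation / centering columns."""
    return gp.add_analysis_columns(default_cohort)


@pytest.fixture(scope="session")
def large_analysis_cohort():
    """A 2000-person cohort for sign/recovery checks."""
    df = gp.generate_cohort(gp.GeneratorConfig(seed=7, n=2000))
    return gp.add_analysis_columns(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
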
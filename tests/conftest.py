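import numpy as np
import pytest

import biofabopt as b


@pytest.fixture(scope="session")
def study():
    """The bundled 30-run yield study."""
    return b.load_yield_study()


@pytest.fixture(scope="session")
def quad_fit(study):
    return b.fit_ols(study, "quadratic")


@pytest.fixture(scope="session")
def anova_table(study, quad_fit):
    return b.anova(quad_fit, study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
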
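import numpy as np
import pytest

from bfgmplx import JointParams, PLxParams, builtin_dataset


@pytest.fixture(scope="session")
def diabetes():
    """The bundled 19-pair duration-of-diabetes / serum-creatinine data."""
    return builtin_dataset()


@pytest.fixture(scope="session")
def table1_truth():
    """First simulation configuration (positive dependence)."""
    return JointParams(PLxParams(0.6, 3.0, 2.8), PLxParams(0.9, 2.5, 0.7), 0.4)


@pytest.fixture(scope="session")
def table2_truth():
    """Second simulation configuration (positive dependence)."""
    return JointParams(PLxParams(1.3, 5.0, 1.5), PLxParams(0.9, 4.0, 1.3), 0.4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
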
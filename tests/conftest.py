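import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ciderdry as cd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: latent dryness equation used for recovery/significance simulations: same
#: five routine variables as the shipped equation, with coefficients sized so
#: every per-variable contribution SD is well above the panel noise floor
RECOVERY_EQUATION = cd.DrynessEquation(
    intercept=10.0,
    coefficients={
        "ph": -2.0,
        "titratable_acidity": 3.0,
        "abs280": -2.0,
        "abs320": -6.0,
        "residual_sugar": 0.0005,
    },
)


@pytest.fixture(scope="session")
def table4():
    return cd.load_fixture("table4")


@pytest.fixture(scope="session")
def table7():
    return cd.load_fixture("table7")


@pytest.fixture(scope="session")
def small_chemistry():
    """A reproducible 30-sample synthetic chemistry table."""
    return cd.generate_chemistry(cd.SyntheticConfig(n_samples=30, seed=11))


def random_regression(seed, n=12, p=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y
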
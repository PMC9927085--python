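import numpy as np
import pytest

from phageburst import BurstParams

#: Parameters of the sigmoid fitted to the study-scale mean burst curve.
FITTED = BurstParams(k_max=1430.0, lt50=119.0, r=0.027, delay=25.0)


def random_params(rng: np.random.Generator) -> BurstParams:
    """A random draw from a broad box of valid model parameters."""
    delay = rng.uniform(0.0, 60.0)
    return BurstParams(
        k_max=rng.uniform(50.0, 5000.0),
        lt50=delay + rng.uniform(20.0, 300.0),
        r=rng.uniform(0.005, 0.1),
        delay=delay,
    )


@pytest.fixture
def fitted_params() -> BurstParams:
    return FITTED


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
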
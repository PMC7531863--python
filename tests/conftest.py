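import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from nucleoseg import (  # noqa: E402
    AlgorithmParams,
    PhantomSpec,
    generate,
    segment_volume,
)


@pytest.fixture(scope="session")
def params() -> AlgorithmParams:
    return AlgorithmParams()


@pytest.fixture(scope="session")
def default_phantom():
    """Demo-scale phantom under the default (noisy) imaging conditions."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return generate(PhantomSpec(seed=7, noise_sigma=0))


@pytest.fixture(scope="session")
def default_masks(default_phantom, params):
    stack, _ = default_phantom
    return segment_volume(stack, params)


@pytest.fixture(scope="session")
def noise_free_masks(noise_free_phantom, params):
    stack, _ = noise_free_phantom
    return segment_volume(stack, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
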
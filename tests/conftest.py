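import numpy as np
import pytest

from chorostrat import (
    PhantomSpec,
    PipelineConfig,
    extract_roi,
    flat_phantom_spec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-noise phantom with mildly curved boundaries."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_flat_phantom():
    """A noise-free phantom with flat boundaries (exact-recovery fixture)."""
    return generate_phantom(flat_phantom_spec(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def default_window(default_phantom):
    return extract_roi(default_phantom.image, default_phantom.roi)


@pytest.fixture()
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240130)
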
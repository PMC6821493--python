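import pytest

from synapsequant.standardize import build_template
from synapsequant.synthgen import SimConfig

SPACING = (1.0, 0.34, 0.34)


@pytest.fixture(scope="session")
def template():
    """The default 6628-voxel half-spheroid template (calibration is cached)."""
    return build_template()


@pytest.fixture
def quiet_config():
    """Single-frame, noise-free acquisition settings."""
    return SimConfig(n_frames=1, poisson_scale=0.0, gaussian_sd=0.0, seed=0)
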
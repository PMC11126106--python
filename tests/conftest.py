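import numpy as np
import pytest

from thyrospec.hsi_io import HyperCube
from thyrospec.synthgen import SynthParams, synth_case, synth_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cube(rng):
    data = rng.integers(0, 4096, size=(6, 5, 12)).astype(np.uint16)
    return HyperCube(data, np.linspace(400, 1000, 12))


@pytest.fixture(scope="session")
def tiny_params():
    """A very small scene for fast case-level tests."""
    return SynthParams.desk(rows=80, cols=80, n_bands=32,
                            nodule_radius=(16.0, 22.0), border_px=6)


@pytest.fixture(scope="session")
def tiny_case(tiny_params):
    return synth_case(tiny_params, "malignant", seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return synth_cohort(3, 3, tiny_params, seed=5)
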
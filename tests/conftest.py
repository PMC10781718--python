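import numpy as np
import pytest

from tmjvol.frames import LandmarkSet, build_reference_frame
from tmjvol.synth import PhantomSpec, make_phantom_series
from tmjvol.volumetry import measure_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def canonical_landmarks():
    return LandmarkSet(PhantomSpec(seed=0).canonical_landmarks())


@pytest.fixture(scope="session")
def canonical_frame(canonical_landmarks):
    return build_reference_frame(canonical_landmarks)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_series(default_spec):
    return make_phantom_series(default_spec)


@pytest.fixture(scope="session")
def default_measurements(default_series):
    """Full-pipeline measurements of the default sagging phantom at h=0.3."""
    return measure_series(default_series.cases, "R", h=0.3)
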
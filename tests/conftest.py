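import numpy as np
import pytest

from conspace.phantom import BundleSpec, PhantomSpec, make_fiber_phantom
from conspace.tracking import TrackingParams


@pytest.fixture(scope="session")
def straight_phantom():
    """Single straight x-axis bundle on a 30^3 grid, identity affine."""
    spec = PhantomSpec(
        shape=(30, 30, 30),
        bundles=[BundleSpec(kind="straight", axis=0, radius=1)],
        seed=11,
    )
    return make_fiber_phantom(spec)


@pytest.fixture(scope="session")
def crossing_phantom():
    """Two straight bundles crossing at 90 degrees with 0.5/0.5 fractions."""
    spec = PhantomSpec(
        shape=(30, 30, 30),
        bundles=[
            BundleSpec(kind="straight", axis=0, radius=1, fraction=0.5),
            BundleSpec(kind="straight", axis=1, radius=1, fraction=0.5),
        ],
        seed=7,
    )
    return make_fiber_phantom(spec)


@pytest.fixture
def fast_params():
    return TrackingParams(samples_per_seed=10, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
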
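import numpy as np
import pytest

from petdenoise.phantom import (
    ActivityVolume,
    EllipsoidSpec,
    LesionSpec,
    PhantomSpec,
    ScannerCalib,
    build_phantom,
)


@pytest.fixture(scope="session")
def calib():
    return ScannerCalib()


@pytest.fixture(scope="session")
def small_spec():
    """A compact phantom with a liver and one lesion, fast to simulate."""
    return PhantomSpec(
        shape=(31, 48, 48),
        background_suv=0.7,
        liver=EllipsoidSpec(center=(15.0, 24.0, 24.0), semi_axes_mm=(14.0, 34.0, 34.0), suv=2.0),
        lesions=(LesionSpec(center=(6.0, 10.0, 36.0), diameter_mm=14.0, suv=3.8),),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
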
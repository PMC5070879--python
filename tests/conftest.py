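import numpy as np
import pytest

from jard.model import AcquisitionScheme, DTMParams
from jard.synthetic import make_scheme


@pytest.fixture(scope="session")
def full_scheme() -> AcquisitionScheme:
    """The canonical acquisition: 92 directions x {1000, 3000} + 2 b0."""
    return make_scheme()


@pytest.fixture(scope="session")
def small_scheme() -> AcquisitionScheme:
    """A cheap 6-direction single-shell scheme plus one b0 for unit tests."""
    g = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
        ],
        dtype=float,
    )
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    b = np.array([0.0, 1000, 1000, 1000, 3000, 3000, 3000])
    dirs = np.vstack([[0, 0, 1], g])
    return AcquisitionScheme(b, dirs)


@pytest.fixture
def crossing_params() -> DTMParams:
    """Canonical 90-degree crossing with the reference tensor shapes."""
    return DTMParams(
        lambda_par=1.48e-3,
        lambda_perp1=0.15e-3,
        lambda_perp2=0.40e-3,
        alpha1=0.0,
        alpha2=0.0,
        alpha3=0.8 * np.pi,
        alpha4=np.pi / 2,
        f1=0.45,
        f2=0.45,
    )
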
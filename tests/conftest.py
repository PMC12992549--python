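import numpy as np
import pytest

from suppdrive.cage import DemographyParams, ReleaseConfig
from suppdrive.genetics import DriveParams


@pytest.fixture
def dp_measured():
    """Conversion/embryo-resistance rates of a strong drive line."""
    return DriveParams(c_f=0.9, c_m=0.8, e=0.5, f_het=1.0)


@pytest.fixture
def dp_neutral():
    """A genetically inert insertion: no cutting, no deposition, no cost."""
    return DriveParams(c_f=0.0, c_m=0.0, e=0.0, f_het=1.0, germline_cut_rate=0.0)


@pytest.fixture
def dem_default():
    return DemographyParams(ne=200.0, low_density_growth=6.0, capacity=2000)


@pytest.fixture
def release20():
    return ReleaseConfig(p0=0.2, n0=500)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_drive_params(rng, fitness_max=1.2):
    return DriveParams(
        c_f=rng.uniform(),
        c_m=rng.uniform(),
        e=rng.uniform(),
        f_het=rng.uniform(0.0, fitness_max),
        germline_cut_rate=rng.uniform(),
    )
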
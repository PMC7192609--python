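import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dntpkin.curves_io import AcquisitionSchedule
from dntpkin.kinetics import FitConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fitted parameters of the published example curves (blank and 3 pmol dGTP)
BLANK_PARAMS = {"A": 28869.0, "k": 2.0e-4, "F0": 35978.0}
DGTP3_PARAMS = {"A1": 6393.0, "k1": 2.5e-3, "A2": 23485.0, "k2": 1.1e-4, "F0": 35540.0}


@pytest.fixture
def split_schedule():
    """Split-time acquisition: 100 cycles of 13 s, then 200 of 80 s."""
    return AcquisitionSchedule(((100, 13.0), (200, 80.0)))


@pytest.fixture
def short_schedule():
    """Uniform 17 s sampling for ~1500 s."""
    return AcquisitionSchedule(((89, 17.0),))


@pytest.fixture
def fit_config():
    return FitConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
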
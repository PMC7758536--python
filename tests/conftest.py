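import numpy as np
import pytest

from restfc.core import RoiTimeSeries
from restfc.synthetic import CohortConfig, NoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """A well-behaved 60-frame, 6-ROI series."""
    data = rng.standard_normal((60, 6))
    return RoiTimeSeries(data, 2.8, [f"ROI_{k}" for k in range(6)], "sub-test")


@pytest.fixture
def tiny_cohort_config():
    """Small, fast cohort with clean (noise-free) signals."""
    return CohortConfig(
        n_per_group=(4, 4, 4),
        n_roi=8,
        n_frames=60,
        noise_spec=NoiseSpec(leak_fraction=0.0, drift_amplitude=0.0),
        seed=7,
    )
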
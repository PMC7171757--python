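import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radsurv.io import ImageVolume, RoiMask
from radsurv.synthetic import CohortSpec, cohort_feature_table, generate_cohort

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_roi(intensities, spacing=(1.0, 1.0, 1.0), mask=None, sequence="T1CE"):
    """Volume + mask pair from a raw array (full mask by default)."""
    arr = np.asarray(intensities, dtype=float)
    vol = ImageVolume(arr, spacing, sequence)
    m = RoiMask(np.ones(arr.shape, dtype=bool) if mask is None else np.asarray(mask))
    return vol, m


def ball_mask(shape, center, radius_vox):
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox**2


@pytest.fixture(scope="session")
def cohort93():
    """One 93-patient synthetic cohort shared by the slower tests."""
    return generate_cohort(CohortSpec(n_patients=93, seed=42))


@pytest.fixture(scope="session")
def table93(cohort93):
    return cohort_feature_table(cohort93)
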
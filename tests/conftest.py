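import numpy as np
import pytest

from autosegeval import BinaryMask, CohortConfig, generate_cohort, metrics_for_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-design cohort (20 patients, 2 systems, 3 observers, 5
    organs, 96^3 grid at 2 mm) with the heavy-patient outlier scenario on
    patient 0; shared across the expensive design-arithmetic checks."""
    cfg = CohortConfig(outlier_patient=0, seed=20240)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    return metrics_for_cohort(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


def random_blob(shape, spacing, rng, frac=85):
    """Random smooth blob mask for metric oracle tests."""
    from scipy import ndimage

    while True:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3)
        m = f > np.percentile(f, frac)
        if m.sum() >= 5:
            return BinaryMask(m, spacing)
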
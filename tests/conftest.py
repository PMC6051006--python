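import numpy as np
import pytest

from eegbands.features import build_feature_table
from eegbands.synth import default_params, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def cohort_seed0():
    """One full calibrated cohort (232 + 218 epochs), shared across tests."""
    cohort, manifest = generate_cohort(default_params(seed=0))
    return cohort, manifest


@pytest.fixture(scope="session")
def features_seed0(cohort_seed0):
    cohort, _ = cohort_seed0
    table, rejects = build_feature_table(cohort)
    assert not rejects
    return table


@pytest.fixture(scope="session")
def small_uncalibrated_cohort():
    """30 + 30 epochs, no measurement calibration — fast directional checks."""
    params = default_params(
        seed=7,
        n_epochs_per_group={"encephalopathy": 30, "normal": 30},
        calibrate=False,
    )
    return generate_cohort(params)
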
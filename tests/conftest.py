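import numpy as np
import pytest
from sklearn.datasets import make_blobs

from psamnmf.motion_io import PipelineConfig
from psamnmf.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def wearable_cohort():
    """Six-subject wearable cohort (72 trials), mixed severe / non-severe."""
    return generate_cohort(CohortSpec(n_subjects=6, seed=3))


@pytest.fixture(scope="session")
def camera_cohort():
    """Three-subject camera cohort (36 trials): 9 feature + 4 trunk markers."""
    return generate_cohort(CohortSpec(n_subjects=3, device="camera", seed=4))


@pytest.fixture(scope="session")
def wearable_cfg():
    return PipelineConfig(device_profile="wearable")


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs (separation 10 sigma), n=60."""
    X, y = make_blobs(
        n_samples=60, centers=[[0.0] * 5, [10.0] * 5], cluster_std=1.0,
        random_state=0,
    )
    return X, y
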
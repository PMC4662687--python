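import numpy as np
import pytest

from stressfuse import generate_protocol, synthesize_recording
from stressfuse.synthetic_data import SubjectParams


@pytest.fixture(scope="session")
def small_schedule():
    return generate_protocol(n_trials=4, picture_s=3, n_pictures=4,
                             fixation_s=10, class_balance=0.5, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_schedule):
    params = SubjectParams(seed=11, artifact_rate_per_min=0.0)
    return synthesize_recording(small_schedule, params, subject_id="S01")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
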
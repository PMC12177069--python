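import numpy as np
import pytest

from gaitdbs import pipeline, synthetic
from gaitdbs.types import StimSetting


@pytest.fixture(scope="session")
def subject():
    return synthetic.SubjectConfig(
        subject_id="S1",
        hemispheres=2,
        safe_range=np.array([[4.1, 5.5], [60.0, 190.0], [60.0, 90.0]]),
        clock_offset_s=-1.7,
    )


@pytest.fixture(scope="session")
def surface(subject):
    return synthetic.build_surface(subject, seed=7)


@pytest.fixture(scope="session")
def trial(subject, surface):
    setting = StimSetting(4.8, 130.0, 70.0)
    return synthetic.simulate_trial(subject, surface, setting, n_strides=20, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.default_cohort_config(
        n_subjects=3, n_visits=1, settings_per_visit=3, n_strides=12
    )
    return synthetic.simulate_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def trial_gait(trial):
    return pipeline.process_trial_gait(trial)
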
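import numpy as np
import pytest

from eegfuse.preprocess import Trial
from eegfuse.synth import Cohort, CohortSpec, generate_cohort


def make_trial(samples=None, fs=200.0, seconds=8.0, label="neutral",
               subject="S01", session=1, trial=1, seed=0):
    if samples is None:
        rng = np.random.default_rng(seed)
        samples = rng.standard_normal((62, int(seconds * fs)))
    return Trial(subject_id=subject, session_id=session, trial_id=trial,
                 samples=samples, sampling_rate=fs, label=label)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """6 subjects (2 per nationality), 6 trials each over 2 sessions,
    12-s trials: enough structure for pipeline and LOSOCV tests while
    staying fast."""
    spec = CohortSpec(
        n_subjects_per_nationality={"Chinese": 2, "French": 2, "German": 2},
        trials_per_subject=6, sessions=2, trial_seconds=12.0,
        emotion_effects={("positive", "gamma"): 1.5, ("negative", "gamma"): 0.7},
        trial_sd=0.0, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    import warnings

    from eegfuse.pipeline import prepare_features

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prepare_features(small_cohort, sequence_length=3)
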
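import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mgsms import pipeline, synth

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# pingouin's two-way epsilon caveat fires on every call; not actionable here
warnings.filterwarnings(
    "ignore", message="Epsilon values might be innaccurate", category=UserWarning
)


@pytest.fixture(scope="session")
def templates():
    return synth.make_template_prototypes()


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic study shared by read-only tests."""
    cfg = synth.TaskConfig(n_subjects=2, n_trials=24, seed=11)
    truth = synth.default_ground_truth()
    return cfg, truth, synth.simulate_session(cfg, truth)


@pytest.fixture(scope="session")
def small_study(small_session):
    cfg, truth, session = small_session
    return cfg, truth, session, pipeline.run_study(cfg, truth, session=session)


def epoch_planted_labels(cfg, subject_data, trial, fs=None):
    """Planted labels restricted to the analysis epoch of one trial."""
    fs = fs or cfg.fs_eeg
    pre = int(round(0.5 * fs))
    nep = int(round(2.3 * fs))
    start = int(np.ceil(cfg.fix_dur * fs)) - pre
    return subject_data.planted_labels[trial].labels[start : start + nep]
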
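import numpy as np
import pytest
from hypothesis import settings

import pupilscreen as ps
from pupilscreen.trial_io import Group, Trial

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True
)
settings.load_profile("suite")


def make_trial(pupil, sample_period_ms=1.0, subject_id="s1", trial_id="t1",
               t0=0.0):
    pupil = np.asarray(pupil, dtype=float)
    t = t0 + np.arange(len(pupil)) * sample_period_ms
    return Trial(subject_id, trial_id, t, pupil, sample_period_ms)


def make_reduced_trial(fn, duration_ms=8000, period_ms=16, **kw):
    """Build a reduced-scale trial from a function of time in ms."""
    t = np.arange(0, duration_ms, period_ms, dtype=float)
    return make_trial(fn(t), sample_period_ms=period_ms, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strong_cohort():
    """A scaled-down strong-effect cohort: full 8 s / 1 kHz trial layout,
    50 subjects, 6 trials each."""
    cfg = ps.scaled_demo_config(effect="strong", trials_per_subject=6,
                                seed=1)
    cohort, truth = ps.generate_cohort(cfg)
    clean, _ = ps.preprocess_cohort(cohort)
    return clean, truth


@pytest.fixture(scope="session")
def strong_fm(strong_cohort):
    clean, _ = strong_cohort
    return ps.build_feature_matrix(clean)


@pytest.fixture
def small_fm(rng):
    """24-subject, 6-feature matrix with one informative feature."""
    n = 24
    labels = [Group.ADHD_POSITIVE] * (n // 2) + [Group.CONTROL] * (n // 2)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    values = rng.normal(size=(n, 6))
    values[:, 0] += 2.0 * y
    return ps.FeatureMatrix(
        subject_ids=[f"s{i}" for i in range(n)],
        labels=labels,
        feature_names=[f"f{i}" for i in range(6)],
        values=values,
    )
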
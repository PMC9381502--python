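"""Shared fixtures: synthetic trials fitted once per session."""

import pytest

from ankleaxis.model import AnkleAxisModel
from ankleaxis.synthetic import WalkConfig, gen_walking_trial

# Stance of 200 camera frames at 240 Hz: every percent of stance falls on a
# frame, so time normalization does not interpolate between frames and the
# noise-free pipeline is exact. Used by the exactness checks.
HINGE_CONFIG = WalkConfig(
    seed=0,
    stance_duration_s=200.0 / 240.0,
    stride_time_s=1.3,
    axis_schedule=((0.0, 10.0, 85.0), (100.0, 10.0, 85.0)),
    flexion_keyframes=((0.0, 0.0), (50.0, -15.0), (97.0, 12.0), (100.0, 12.0)),
)


def fit_single(trial, standing, **kwargs):
    kwargs.setdefault("qc", False)
    model = AnkleAxisModel([trial], standing, **kwargs)
    return model.fit()


@pytest.fixture(scope="session")
def hinge_fitted():
    """Noise-free hinge trial (constant axis incl 10, dev 85), no filter."""
    trial, standing, truth = gen_walking_trial(HINGE_CONFIG)
    results = fit_single(trial, standing, lowpass_cutoff_hz=None)
    return results, truth


@pytest.fixture(scope="session")
def default_noiseless():
    """Default walking config (varying axis schedule), sigma = 0."""
    trial, standing, truth = gen_walking_trial(WalkConfig(seed=11))
    results = fit_single(trial, standing, lowpass_cutoff_hz=None)
    return results, truth


@pytest.fixture(scope="session")
def default_generated():
    return gen_walking_trial(WalkConfig(seed=11))


def single_trial_windows(results):
    return next(iter(results.trial_windows.values()))
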
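"""Shared fixtures: profiles, clean/noisy trials, reconstructed traces."""
from dataclasses import replace

import pytest

import gait5m as g


@pytest.fixture(scope="session")
def hc_profile():
    return g.make_group_profile("HC", 1.0)


@pytest.fixture(scope="session")
def pd_profile():
    return g.make_group_profile("PD", 1.0)


@pytest.fixture(scope="session")
def clean_profile(hc_profile):
    """Noise-free, tilt-free healthy-control profile."""
    return replace(hc_profile, noise_sd_acc=0.0, noise_sd_gyro=0.0,
                   sensor_tilt_deg=0.0)


@pytest.fixture(scope="session")
def clean_trial(clean_profile):
    return g.simulate_trial(clean_profile, "SS", seed=1)


@pytest.fixture(scope="session")
def clean_trace(clean_trial):
    return g.reconstruct_trial(clean_trial[0])


@pytest.fixture(scope="session")
def noisy_trial(hc_profile):
    """Default-noise, tilted trial (the study's nominal recording)."""
    return g.simulate_trial(hc_profile, "SS", seed=2)


@pytest.fixture(scope="session")
def noisy_trace(noisy_trial):
    return g.reconstruct_trial(noisy_trial[0])


@pytest.fixture(scope="session")
def segmented(noisy_trial, noisy_trace):
    return g.segment_trial(noisy_trace)
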
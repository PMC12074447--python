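"""Shared fixtures: small simulated recordings built at test time."""

import numpy as np
import pytest

from fetalmotion.synthetic import SimConfig, simulate_calibration, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A 30 s default-world trial with its ground truth."""
    cfg = SimConfig(trial_duration=30.0)
    return simulate_trial(cfg, seed=7)


@pytest.fixture(scope="session")
def small_calibration():
    cfg = SimConfig(trial_duration=30.0)
    return simulate_calibration(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def noiseless_config(**kw) -> SimConfig:
    base = dict(
        trial_duration=30.0,
        noise_sd_acc=0.0,
        noise_sd_gyr=0.0,
        drift_scale=0.0,
    )
    base.update(kw)
    return SimConfig(**base)
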
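"""Shared fixtures: small synthetic recordings and cycle banks."""

import numpy as np
import pytest

from ppgvitals.siggen import SimConfig, generate_recording


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, drift-free, fixed-rate recording configuration."""
    return SimConfig(fs=125, duration=30, hr=72, rr=15, spo2=97, noise_sd=0.0, drift_amp=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_recording(clean_cfg):
    return generate_recording(clean_cfg)


@pytest.fixture(scope="session")
def noisy_recording():
    cfg = SimConfig(fs=125, duration=30, hr=75, rr=15, spo2=96, noise_sd=0.02, seed=3)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def small_cycle_bank():
    """~120 detrended cycle pairs from a few synthetic sessions."""
    from ppgvitals.benchmarks import make_cycle_bank

    return make_cycle_bank(120, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
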
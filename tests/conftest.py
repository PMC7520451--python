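import dataclasses

import numpy as np
import pytest

import suctionpower as sp


@pytest.fixture(scope="session")
def clean_bundle():
    """Noiseless synthetic strike: the zero-noise fixed point."""
    truth = sp.SyntheticTruth(seed=0, noise_sigma_mm=0.0, pressure_noise_frac=0.0)
    return sp.simulate_strike(truth)


@pytest.fixture(scope="session")
def clean_analysis(clean_bundle):
    """Noiseless strike analyzed with filtering disabled (exact recovery)."""
    b = clean_bundle
    cfg = dataclasses.replace(b.config, filters=sp.FilterSettings(None, None))
    return sp.analyze_strike(cfg, b.bones, b.trajectories,
                             b.pressure_time_s,
                             b.pressure_raw_mv * b.config.pressure_calibration_pa_per_mv)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Synthetic strike at the 0.08 mm tracking-precision noise scale."""
    return sp.simulate_strike(sp.SyntheticTruth(seed=7))


@pytest.fixture(scope="session")
def noisy_analysis(noisy_bundle):
    b = noisy_bundle
    return sp.analyze_strike(b.config, b.bones, b.trajectories,
                             b.pressure_time_s,
                             b.pressure_raw_mv * b.config.pressure_calibration_pa_per_mv)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
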
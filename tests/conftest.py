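import numpy as np
import pytest

from driveload.synthetic import (
    GeneratorConfig,
    simulate_recording,
    simulate_route,
    simulate_telemetry,
)


@pytest.fixture(scope="session")
def short_route():
    return simulate_route(1500.0, seed=7)


@pytest.fixture(scope="session")
def short_telemetry(short_route):
    return simulate_telemetry(short_route, seed=8)


@pytest.fixture(scope="session")
def noisy_recording(short_route, short_telemetry):
    """~60 s of realistic data: background, oscillations, EOG, ERPs."""
    cfg = GeneratorConfig(snr=5.0)
    return simulate_recording(short_route, short_telemetry, cfg, seed=9)


@pytest.fixture(scope="session")
def clean_recording(short_route, short_telemetry):
    """Neural components only: no background, oscillations or EOG."""
    cfg = GeneratorConfig(snr=None, include_oscillations=False,
                          include_eog=False)
    return simulate_recording(short_route, short_telemetry, cfg, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
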
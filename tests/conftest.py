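import numpy as np
import pytest

from driven.synthetic_psg import DEFAULT_CHANNEL_RATES, SimParams, simulate_recording

#: low-rate channel map used wherever waveform bandwidth does not matter
FAST_RATES = {"abdominal": 8, "thoracic": 8, "airflow": 8, "spo2": 1, "ecg": 128}


@pytest.fixture(scope="session")
def short_night():
    """A 30 min all-sleep night with a moderate event load."""
    params = SimParams(
        duration_h=0.5,
        sleep_fraction=1.0,
        target_ahi=20.0,
        channel_rates=dict(FAST_RATES),
        seed=42,
    )
    return simulate_recording(params)


@pytest.fixture(scope="session")
def full_night():
    """A 2 h night with awakenings, used for labeling and estimation tests."""
    params = SimParams(
        duration_h=2.0,
        sleep_fraction=0.85,
        target_ahi=25.0,
        channel_rates=dict(FAST_RATES),
        seed=7,
    )
    return simulate_recording(params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
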
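import numpy as np
import pytest

from stncc import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def time_axis_250():
    """Standard epoch grid: -200..500 ms at 250 Hz (176 samples)."""
    return np.arange(-50, 126) * 4.0


@pytest.fixture
def small_session():
    """Reduced session for fast end-to-end tests (explicit 1 kHz raw rate)."""
    return SessionConfig(
        raw_rate=1000.0,
        n_trials_per_condition={"vis_only": 12, "ipsi": 12,
                                "contra": 12, "tms_only": 6},
        seed=42,
    )
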
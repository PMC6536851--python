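import numpy as np
import pytest

from microdyn import (
    average_reference,
    epoch_and_select,
    make_topographies,
    simulate_microstate_eeg,
)


@pytest.fixture(scope="session")
def templates32():
    """Five well-separated 32-channel templates."""
    return make_topographies(32, 5, seed=11)


@pytest.fixture(scope="session")
def clean_subject(templates32):
    """Noise-free 20-s recording with planted 80-ms dwell + its truth."""
    rec, truth = simulate_microstate_eeg(
        templates32, dwell_mean_ms=80.0, fs=256.0, duration_s=20.0,
        carrier_hz=10.0, snr=np.inf, seed=21,
    )
    return rec, truth


@pytest.fixture(scope="session")
def clean_epochs(clean_subject):
    rec, _ = clean_subject
    return epoch_and_select(average_reference(rec), epoch_s=2.0, n_keep=10)
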
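import numpy as np
import pytest

from rsvp_alpha.pipeline import simulate_calibration
from rsvp_alpha.preprocess import EpochSet, epoch, preprocess
from rsvp_alpha.sim import NONTARGET


@pytest.fixture(scope="session")
def small_calibration():
    """A 20-trial 1 Hz reference calibration, preprocessed, with both
    epoch sets cut; shared by tests that only need realistic data."""
    schedule, rec = simulate_calibration(1.0, 20, seed=11)
    pre = preprocess(rec)
    return {
        "schedule": schedule,
        "recording": rec,
        "pre": pre,
        "tf_epochs": epoch(pre, (-1250.0, 1250.0)),
        "erp_epochs": epoch(pre, (-200.0, 800.0)),
    }


def tone_epochs(freq_hz, fs=150.0, n_samples=375, n_epochs=1, amp=1.0,
                window_ms=(-1250.0, 1250.0), channel="POOL"):
    """Epochs containing a pure sinusoid; used as spectral/wavelet oracle
    input."""
    t = np.arange(n_samples) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_epochs, 1, 1))
    return EpochSet(data=data, window_ms=window_ms, fs=fs,
                    labels=np.array([NONTARGET] * n_epochs, dtype=object),
                    channels=(channel,))
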
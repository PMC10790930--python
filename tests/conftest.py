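import numpy as np
import pytest

from errpnav.containers import EpochSet
from errpnav.montages import get_montage
from errpnav.preprocess import extract_interest_window, preprocess_recording
from errpnav.simulate import ErrPModel, generate_recording


@pytest.fixture(scope="session")
def dry20():
    return get_montage("dry20")


@pytest.fixture(scope="session")
def gel16():
    return get_montage("gel16")


@pytest.fixture(scope="session")
def default_recording(dry20):
    """200-trial balanced dry-20 recording with the default ErrP effect."""
    return generate_recording(dry20, ErrPModel(), n_trials=200,
                              error_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def default_epochs(default_recording):
    """Preprocessed full epochs (-0.2 to 1.0 s at 250 Hz)."""
    return preprocess_recording(default_recording)


@pytest.fixture(scope="session")
def interest_epochs(default_epochs):
    """Interest-window epochs (0.2-0.8 s, 150 samples)."""
    return extract_interest_window(default_epochs)


def make_epochs(data, labels, rate=250.0, names=None, tz=0):
    """Small helper to build an EpochSet from raw arrays."""
    data = np.asarray(data, dtype=float)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data=data, labels=np.array(labels, dtype=object),
                    rate=rate, channel_names=names, time_zero_index=tz)
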
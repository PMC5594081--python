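import numpy as np
import pytest

from chronnect.preprocess import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_recording(freqs, fs=160.0, duration=10.0, amp=1.0):
    """Multi-channel recording, one pure sine per channel."""
    t = np.arange(int(duration * fs)) / fs
    data = np.vstack([amp * np.sin(2 * np.pi * f * t) for f in freqs])
    if data.shape[0] < 2:
        data = np.vstack([data, data])
    labels = [f"CH{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, labels=labels)


@pytest.fixture
def tiny_coupled_recording():
    """4-channel, 20 s recording with a planted theta coupling on (0, 1)."""
    from chronnect.synthgen import (
        CouplingSpecification, Epoch, PlantedCoupling, gen_coupled_eeg,
    )

    spec = CouplingSpecification(
        epochs=(Epoch(20.0, (PlantedCoupling(pair=(0, 1), label=2, strength=1.0),)),),
        snr_db=10.0,
    )
    rec, _ = gen_coupled_eeg(spec, n_channels=4, fs=160.0, seed=11)
    return rec
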
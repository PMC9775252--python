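import numpy as np
import pytest

from plvnet import BAND_BY_NAME, EEGRecording, SimulationConfig
from plvnet.synthdata import CouplingSpec


def sine_recording(freqs, fs=500.0, duration=12.0, labels=None, amp=1.0):
    """Multichannel recording of pure sinusoids (one frequency per channel)."""
    t = np.arange(int(duration * fs)) / fs
    data = np.array([amp * np.sin(2 * np.pi * f * t) for f in freqs])
    labels = labels or tuple(f"ch{i}" for i in range(len(freqs)))
    return EEGRecording(data, fs, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Tiny but structurally complete cohort config for fast tests."""
    return SimulationConfig(
        n_per_group=2,
        seed=7,
        segment_layout=(("pre", 12.0), ("music", 4.0), ("post", 12.0)),
    )


def single_band_config(band_name, strength, n_channels=4, duration=20.0,
                       seed=0, noise_sd=0.0, jitter=0.0, layout_condition="pre"):
    """Config coupling all channels in one band only."""
    band = BAND_BY_NAME[band_name]
    labels = tuple(f"ch{i}" for i in range(n_channels))
    coupling = {
        (g, layout_condition, band_name): CouplingSpec(band, strength,
                                                       phase_jitter_sd=jitter)
        for g in ("MDD", "HC")
    }
    return SimulationConfig(
        n_per_group=1, seed=seed, channel_labels=labels,
        segment_layout=((layout_condition, duration),),
        band_coupling=coupling, noise_sd=noise_sd,
        subject_strength_sd=0.0,
    )
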
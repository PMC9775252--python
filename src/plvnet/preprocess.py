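"""Raw-recording conditioning: channel selection, common average reference,
zero-phase FIR band filtering, condition segmentation and band decomposition.

All operations are pure: they return new :class:`EEGRecording` objects and
never mutate their input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientDataError,
    InvalidBandError,
    MissingChannelError,
    TooShortError,
)

#: The 19 scalp channels retained for whole-head connectivity analysis
#: (10-20 montage labels, fixed order).
CHANNELS_19 = (
    "Fp1", "Fp2", "Fpz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8",
    "Pz", "P3", "P4", "P7", "P8", "O1", "O2",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_at(self, sampling_rate: float) -> None:
        """Raise if the band does not fit under the Nyquist frequency."""
        if self.high >= sampling_rate / 2:
            raise InvalidBandError(
                f"band {self.name!r} ({self.low}-{self.high} Hz) exceeds "
                f"Nyquist {sampling_rate / 2} Hz"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Canonical EEG analysis bands.
CANONICAL_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)
BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class EEGRecording:
    """A channels x samples block of multichannel signal.

    Parameters
    ----------
    data
        2-D float array, one row per channel. Microvolt scale for real
        EEG; unitless for synthetic signals.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        Ordered montage labels, one per row.
    meta
        Free-form provenance mapping (never interpreted by the pipeline).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class ConditionSegment:
    """A contiguous slice of a session assigned to one experimental condition."""

    recording: EEGRecording
    condition: str
    start: float
    duration: float


def _fir_bandpass(low: float, high: float, sampling_rate: float) -> np.ndarray:
    """Hamming-window FIR bandpass taps.

    Transition width is 25% of the lower band edge with a 1 Hz floor,
    which keeps the filter order tractable for sub-hertz edges.
    """
    width = max(1.0, 0.25 * low)
    numtaps = int(math.ceil(3.3 * sampling_rate / width))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return sps.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=sampling_rate
    )


def bandpass_filter(recording: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase (forward-backward) FIR bandpass of every channel.

    Raises
    ------
    InvalidBandError
        If the band lies outside (0, Nyquist).
    TooShortError
        If the recording is shorter than three filter orders.
    """
    band = BandDefinition("bandpass", low, high)
    band.validate_at(recording.sampling_rate)
    taps = _fir_bandpass(low, high, recording.sampling_rate)
    n = recording.n_samples
    if n < 3 * len(taps):
        raise TooShortError(
            f"recording has {n} samples; the ({low}, {high}) Hz filter needs "
            f">= {3 * len(taps)} (order {len(taps) - 1})"
        )
    out = sps.filtfilt(taps, [1.0], recording.data, axis=1,
                       padlen=min(3 * len(taps), n - 1))
    meta = dict(recording.meta)
    meta["bandpass"] = (low, high)
    return replace(recording, data=out, meta=meta)


def common_average_reference(recording: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if recording.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    out = recording.data - recording.data.mean(axis=0, keepdims=True)
    meta = dict(recording.meta)
    meta["reference"] = "common_average"
    return replace(recording, data=out, meta=meta)


def select_channels(recording: EEGRecording, keep=CHANNELS_19) -> EEGRecording:
    """Keep only the requested channels, reordered to the requested order."""
    keep = tuple(keep)
    missing = [c for c in keep if c not in recording.channel_labels]
    if missing:
        raise MissingChannelError(missing)
    idx = [recording.channel_labels.index(c) for c in keep]
    return replace(
        recording, data=recording.data[idx].copy(), channel_labels=keep,
        meta=dict(recording.meta),
    )


def segment_conditions(recording: EEGRecording, layout) -> list[ConditionSegment]:
    """Cut a session into contiguous half-open condition segments.

    ``layout`` is an ordered list of ``(condition_name, duration_seconds)``.
    The boundary sample belongs to the later segment.
    """
    fs = recording.sampling_rate
    total = sum(d for _, d in layout)
    if any(d <= 0 for _, d in layout):
        raise ValueError("all segment durations must be positive")
    if total > recording.duration + 1e-9:
        raise InsufficientDataError(
            f"layout needs {total} s but recording has {recording.duration} s"
        )
    segments: list[ConditionSegment] = []
    start_sample = 0
    start_t = 0.0
    for condition, duration in layout:
        n = int(math.floor(duration * fs))
        sl = recording.data[:, start_sample:start_sample + n]
        seg_rec = replace(
            recording, data=sl.copy(),
            meta={**recording.meta, "condition": condition},
        )
        segments.append(ConditionSegment(seg_rec, condition, start_t, duration))
        start_sample += n
        start_t += duration
    return segments


def decompose_bands(segment: ConditionSegment, bands=CANONICAL_BANDS):
    """Band-limited copy of a segment per band: mapping name -> EEGRecording."""
    out = {}
    for band in bands:
        band.validate_at(segment.recording.sampling_rate)
        filtered = bandpass_filter(segment.recording, band.low, band.high)
        filtered.meta["band"] = band.name
        out[band.name] = filtered
    return out


# ---------------------------------------------------------------------------
# Plain-text recording I/O (columns = channels, one-line label header).

def write_recording_csv(path, recording: EEGRecording, delimiter=",") -> None:
    """Write samples x channels matrix with a channel-label header line."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.9g", delimiter=delimiter)


def read_recording_csv(path, sampling_rate: float, delimiter=",",
                       meta=None) -> EEGRecording:
    """Read a delimited text matrix written by :func:`write_recording_csv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        labels = tuple(h.strip() for h in header.split(delimiter))
        data = np.loadtxt(fh, delimiter=delimiter, ndmin=2)
    return EEGRecording(data.T, sampling_rate, labels, meta=dict(meta or {}))
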
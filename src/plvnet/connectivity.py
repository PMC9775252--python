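"""Instantaneous phase via the Hilbert transform and phase-locking-value
(PLV) adjacency matrices.

The PLV between two phase series is the modulus of the time-averaged unit
phasor of their phase difference,

    PLV = | <exp(i (phi_x(t) - phi_y(t)))>_t |
        = sqrt(<cos dphi>^2 + <sin dphi>^2),

which lies in [0, 1]: 1 for a constant phase relation, 0 for no phase
consistency. The adjacency matrix carries this value for every channel
pair, with the diagonal fixed at 1 (a channel is perfectly synchronized
with itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateSignalError, TooShortError
from .preprocess import (
    CANONICAL_BANDS,
    BandDefinition,
    ConditionSegment,
    EEGRecording,
    decompose_bands,
)

ANALYZED_CONDITIONS = ("pre", "post")


@dataclass
class PhaseSeries:
    """Per-channel instantaneous phase with a per-sample validity mask."""

    phases: np.ndarray              # channels x samples, radians in (-pi, pi]
    valid_mask: np.ndarray          # samples, bool; False near filter edges
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.phases.ndim != 2:
            raise ValueError("phases must be channels x samples")
        if self.valid_mask.shape != (self.phases.shape[1],):
            raise ValueError("valid_mask length must equal sample count")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric PLV adjacency matrix for one (subject, condition, band)."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band: str
    condition: str
    subject_id: str
    n_samples: int
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square, matching channel_labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("values must be symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("PLV entries must lie in [0, 1]")

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle (p < q) PLV values as a flat vector."""
        iu = np.triu_indices(len(self.channel_labels), 1)
        return self.values[iu]


def instantaneous_phase(recording: EEGRecording,
                        edge_exclusion: float = 1.0) -> PhaseSeries:
    """Phase of the analytic signal x + i*H[x], per channel.

    Samples within ``edge_exclusion`` seconds of either end are flagged
    invalid (filter/Hilbert edge effects). Input channels are expected to
    be band-limited; a constant channel has no defined phase and raises
    :class:`DegenerateSignalError`.
    """
    n = recording.n_samples
    edge = int(round(edge_exclusion * recording.sampling_rate))
    if n <= 2 * edge:
        raise TooShortError(
            f"{n} samples cannot accommodate 2 x {edge} edge-excluded samples"
        )
    scale = np.abs(recording.data).max()
    degenerate = recording.data.std(axis=1) <= 1e-12 * max(scale, 1e-300)
    if np.any(degenerate):
        bad = [recording.channel_labels[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateSignalError(
            f"constant channel(s) have undefined phase: {bad}"
        )
    analytic = hilbert(recording.data, axis=1)
    phases = np.angle(analytic)
    phases[phases == -np.pi] = np.pi  # canonical interval (-pi, pi]
    mask = np.ones(n, dtype=bool)
    if edge > 0:
        mask[:edge] = False
        mask[-edge:] = False
    return PhaseSeries(phases, mask, recording.channel_labels)


def plv_from_phase_pair(phase_x, phase_y, mask=None) -> float:
    """PLV of one channel pair: modulus of the mean phase-difference phasor."""
    phase_x = np.asarray(phase_x, dtype=np.float64)
    phase_y = np.asarray(phase_y, dtype=np.float64)
    if phase_x.shape != phase_y.shape:
        raise ValueError(
            f"phase series lengths differ: {phase_x.shape} vs {phase_y.shape}"
        )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        phase_x, phase_y = phase_x[mask], phase_y[mask]
    if phase_x.size < 2:
        raise ValueError("need at least 2 valid samples")
    dphi = phase_x - phase_y
    plv = np.hypot(np.cos(dphi).mean(), np.sin(dphi).mean())
    return float(min(plv, 1.0))  # guard against one-ulp overshoot


def plv_matrix(phases: PhaseSeries, band: str = "", condition: str = "",
               subject_id: str = "", group: str | None = None) -> ConnectivityMatrix:
    """PLV adjacency over all channel pairs; diagonal fixed at 1."""
    if phases.n_channels < 2:
        raise ValueError("need at least 2 channels")
    valid = phases.phases[:, phases.valid_mask]
    if valid.shape[1] < 2:
        raise ValueError("fewer than 2 valid samples")
    phasors = np.exp(1j * valid)
    m = np.abs(phasors @ phasors.conj().T) / valid.shape[1]
    m = 0.5 * (m + m.T)
    np.clip(m, 0.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return ConnectivityMatrix(m, phases.channel_labels, band, condition,
                              subject_id, valid.shape[1], group=group)


def sliding_plv(phase_x, phase_y, window: int, step: int) -> np.ndarray:
    """Optional utility: PLV in sliding windows (not used by the pipeline)."""
    phase_x = np.asarray(phase_x, dtype=np.float64)
    phase_y = np.asarray(phase_y, dtype=np.float64)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series lengths differ")
    phasor = np.exp(1j * (phase_x - phase_y))
    starts = range(0, phase_x.size - window + 1, step)
    return np.array([np.abs(phasor[s:s + window].mean()) for s in starts])


def segment_connectivity(segment: ConditionSegment, bands=CANONICAL_BANDS,
                         edge_exclusion: float = 1.0, subject_id: str = "",
                         group: str | None = None) -> list[ConnectivityMatrix]:
    """Band-decompose one condition segment and build one matrix per band."""
    out = []
    for band_name, band_rec in decompose_bands(segment, bands).items():
        ph = instantaneous_phase(band_rec, edge_exclusion)
        out.append(plv_matrix(ph, band=band_name, condition=segment.condition,
                              subject_id=subject_id, group=group))
    return out


def cohort_connectivity(labeled_segments, bands=CANONICAL_BANDS,
                        edge_exclusion: float = 1.0,
                        conditions=ANALYZED_CONDITIONS) -> list[ConnectivityMatrix]:
    """One ConnectivityMatrix per (subject, analyzed condition, band).

    ``labeled_segments`` is an iterable of (LabeledRecording, ConditionSegment)
    pairs whose recordings have already been referenced and broadband filtered.
    Segments whose condition is outside ``conditions`` are skipped.
    """
    matrices = []
    for labeled, segment in labeled_segments:
        if segment.condition not in conditions:
            continue
        matrices.extend(
            segment_connectivity(segment, bands, edge_exclusion,
                                 subject_id=labeled.subject_id,
                                 group=labeled.group)
        )
    return matrices


def mean_matrices(matrices) -> dict:
    """Group-averaged matrices keyed by (group, condition, band)."""
    buckets: dict = {}
    for m in matrices:
        key = (m.group, m.condition, m.band)
        buckets.setdefault(key, []).append(m)
    out = {}
    for key, ms in buckets.items():
        stack = np.mean([m.values for m in ms], axis=0)
        out[key] = ConnectivityMatrix(
            stack, ms[0].channel_labels, ms[0].band, ms[0].condition,
            subject_id=f"mean[{key[0]}]", n_samples=ms[0].n_samples,
            group=key[0], meta={"n_subjects": len(ms)},
        )
    return out


# ---------------------------------------------------------------------------
# Matrix I/O: labelled CSV per matrix, and a long-format TSV across a cohort.

def write_matrix_csv(path, matrix: ConnectivityMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"# subject={matrix.subject_id} group={matrix.group or ''} "
                 f"condition={matrix.condition} band={matrix.band} "
                 f"n_samples={matrix.n_samples}\n")
        fh.write("," + ",".join(matrix.channel_labels) + "\n")
        for label, row in zip(matrix.channel_labels, matrix.values):
            fh.write(label + "," + ",".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix_csv(path) -> ConnectivityMatrix:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        fields = dict(kv.split("=", 1) for kv in header.split())
        labels = fh.readline().strip().split(",")[1:]
        rows = [line.strip().split(",")[1:] for line in fh if line.strip()]
    values = np.array(rows, dtype=np.float64)
    return ConnectivityMatrix(
        values, tuple(labels), fields["band"], fields["condition"],
        fields["subject"], int(fields["n_samples"]),
        group=fields.get("group") or None,
    )


def write_long_tsv(path, matrices) -> None:
    """Long-format (subject, group, condition, band, ch1, ch2, plv) table."""
    with open(path, "w") as fh:
        fh.write("subject\tgroup\tcondition\tband\tch1\tch2\tplv\n")
        for m in matrices:
            n = len(m.channel_labels)
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{m.subject_id}\t{m.group or ''}\t{m.condition}\t"
                             f"{m.band}\t{m.channel_labels[i]}\t"
                             f"{m.channel_labels[j]}\t{m.values[i, j]:.12g}\n")
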
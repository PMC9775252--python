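"""Synthetic multichannel-signal cohorts with controlled band-specific
phase coupling.

The generative model is shared-driver phase mixing: within each band every
coupled channel's unwrapped phase is a convex mixture of a common driver
phase (weight ``strength``) and an independent channel phase (weight
``1 - strength``). Phase tracks are frequency-modulated carriers with a
small Wiener (phase-diffusion) component, so each band signal is narrowband
by construction and the expected pairwise phase-locking value is strictly
increasing in the coupling strength. Band signals are summed per channel
and broadband Gaussian noise is added on top.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, InvalidBandError, TooShortError
from .preprocess import (
    BAND_BY_NAME,
    CHANNELS_19,
    BandDefinition,
    EEGRecording,
    read_recording_csv,
    write_recording_csv,
)

GROUPS = ("MDD", "HC")
CONDITIONS = ("pre", "music", "post")

DEFAULT_LAYOUT = (("pre", 60.0), ("music", 240.0), ("post", 60.0))


@dataclass(frozen=True)
class CouplingSpec:
    """Phase-coupling recipe for one band.

    ``strength`` is the mixing weight kappa in [0, 1]: 0 leaves all channel
    phases independent, 1 makes every coupled channel share the driver
    phase exactly. ``coupled_pairs`` restricts coupling to the channels
    appearing in the given label pairs; coupling via a single shared driver
    means the coupled set closes into a clique (all pairs among the union
    of listed channels end up coupled). ``None`` couples all channels.
    """

    band: BandDefinition
    strength: float
    coupled_pairs: frozenset | None = None
    phase_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigurationError(f"strength must be in [0,1], got {self.strength}")
        if self.phase_jitter_sd < 0:
            raise ConfigurationError("phase_jitter_sd must be >= 0")

    def coupled_channels(self, labels) -> tuple[str, ...]:
        """Channels participating in the coupling, in montage order."""
        if self.coupled_pairs is None:
            return tuple(labels)
        members = {c for pair in self.coupled_pairs for c in pair}
        unknown = members - set(labels)
        if unknown:
            raise ConfigurationError(
                f"coupled_pairs reference unknown channels: {sorted(unknown)}"
            )
        return tuple(c for c in labels if c in members)


def _pairs(channels) -> frozenset:
    chans = tuple(channels)
    return frozenset(
        frozenset((a, b)) for i, a in enumerate(chans) for b in chans[i + 1:]
    )


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_per_group: int
    sampling_rate: float = 500.0
    segment_layout: tuple = DEFAULT_LAYOUT
    channel_labels: tuple[str, ...] = CHANNELS_19
    band_coupling: dict = field(default_factory=dict)
    noise_sd: float = 1.5
    seed: int = 0
    subject_strength_sd: float = 0.01  # per-subject trait jitter on kappa

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel_labels must be unique")
        self.segment_layout = tuple((str(c), float(d)) for c, d in self.segment_layout)
        if any(d <= 0 for _, d in self.segment_layout):
            raise ConfigurationError("all segment durations must be positive")
        if not self.band_coupling:
            self.band_coupling = default_band_coupling()
        highest = max(s.band.high for s in self.band_coupling.values())
        if self.sampling_rate <= 2 * highest:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} must exceed twice the "
                f"highest band edge {highest}"
            )
        for key, spec in self.band_coupling.items():
            spec.coupled_channels(self.channel_labels)  # validates labels
            if len(key) != 3:
                raise ConfigurationError(
                    f"band_coupling keys are (group, condition, band), got {key!r}"
                )

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.segment_layout)

    def duration_of(self, condition: str) -> float:
        for name, dur in self.segment_layout:
            if name == condition:
                return dur
        raise ConfigurationError(f"condition {condition!r} not in segment_layout")


@dataclass
class LabeledRecording:
    """A recording tagged with its cohort metadata."""

    recording: EEGRecording
    subject_id: str
    group: str
    condition: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")


# ---------------------------------------------------------------------------
# Phase-track primitive

def _phase_track(rng: np.random.Generator, n: int, sampling_rate: float,
                 band: BandDefinition, fm_frac: float = 0.4,
                 diffusion_scale: float = 0.6) -> np.ndarray:
    """Unwrapped phase of a narrowband oscillation.

    Instantaneous frequency = band centre + bounded smooth FM deviation
    (``fm_frac`` of the half-width) plus a Wiener phase component with
    diffusion ``diffusion_scale * bandwidth`` rad^2/s. The diffusion term
    sets how fast independent tracks decorrelate, which controls the
    zero-coupling PLV floor.
    """
    m = gaussian_filter1d(rng.standard_normal(n), sampling_rate / band.width,
                          mode="reflect")
    sd = m.std()
    if sd > 0:
        m = m / sd
    freq = band.center + fm_frac * (band.width / 2) * np.tanh(m)
    diffusion = diffusion_scale * band.width
    wiener = np.cumsum(rng.normal(0.0, np.sqrt(diffusion / sampling_rate), n))
    return 2 * np.pi * np.cumsum(freq) / sampling_rate + wiener


def make_narrowband_signal(sampling_rate: float, duration: float,
                           band: BandDefinition, seed: int,
                           envelope_depth: float = 0.25):
    """Single-channel band-limited signal with known ground-truth phase.

    Returns ``(signal, phase)`` where ``phase`` (wrapped to (-pi, pi]) is
    the exact phase used to synthesize the signal, enabling independent
    validation of Hilbert-based phase extraction.
    """
    if band.low <= 0 or band.high >= sampling_rate / 2:
        raise InvalidBandError(
            f"band ({band.low}, {band.high}) outside (0, {sampling_rate / 2})"
        )
    n = int(round(duration * sampling_rate))
    if n < 64:
        raise TooShortError(f"duration x sampling_rate = {n} < 64 samples")
    rng = np.random.default_rng(seed)
    # Gentle FM and diffusion keep >= 90% of power inside the band.
    phase = _phase_track(rng, n, sampling_rate, band,
                         fm_frac=0.3, diffusion_scale=0.1)
    env_mod = gaussian_filter1d(rng.standard_normal(n),
                                2 * sampling_rate / band.width, mode="reflect")
    sd = env_mod.std()
    if sd > 0:
        env_mod = env_mod / sd
    envelope = 1.0 + envelope_depth * np.tanh(env_mod)
    signal = envelope * np.cos(phase)
    wrapped = np.angle(np.exp(1j * phase))
    wrapped[wrapped == -np.pi] = np.pi
    return signal, wrapped


# ---------------------------------------------------------------------------
# Cohort generation

def _subject_strength_offsets(config: SimulationConfig, subject_seed: int) -> dict:
    """Per-subject trait offsets on kappa, stable across conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_seed, 0xBEEF])
    )
    names = sorted({spec.band.name for spec in config.band_coupling.values()})
    return {name: rng.normal(0.0, config.subject_strength_sd) for name in names}


def generate_coupled_recording(config: SimulationConfig, group: str,
                               condition: str, subject_seed: int) -> LabeledRecording:
    """One (subject, condition) recording under the configured coupling."""
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    duration = config.duration_of(condition)
    fs = config.sampling_rate
    n = int(round(duration * fs))
    labels = config.channel_labels
    specs = {
        key[2]: spec for key, spec in config.band_coupling.items()
        if key[0] == group and key[1] == condition
    }
    if not specs:
        raise ConfigurationError(
            f"no band_coupling entries for (group={group!r}, condition={condition!r})"
        )
    offsets = _subject_strength_offsets(config, subject_seed)
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_seed, 1 + cond_idx])
    )
    data = np.zeros((len(labels), n))
    for band_name in sorted(specs):
        spec = specs[band_name]
        kappa = float(np.clip(spec.strength + offsets[spec.band.name], 0.0, 1.0))
        driver = _phase_track(rng, n, fs, spec.band)
        coupled = set(spec.coupled_channels(labels))
        for ci, label in enumerate(labels):
            own = _phase_track(rng, n, fs, spec.band)
            phase = kappa * driver + (1.0 - kappa) * own if label in coupled else own
            if spec.phase_jitter_sd > 0:
                phase = phase + rng.normal(0.0, spec.phase_jitter_sd, n)
            data[ci] += np.cos(phase)
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    recording = EEGRecording(
        data, fs, labels,
        meta={"synthetic": True, "group": group, "condition": condition,
              "subject_seed": subject_seed},
    )
    return LabeledRecording(recording, f"{group}{subject_seed:02d}", group, condition)


def iter_cohort(config: SimulationConfig, conditions=None):
    """Lazily yield labeled recordings for every (group, subject, condition)."""
    conditions = tuple(conditions) if conditions is not None else config.conditions
    for group in GROUPS:
        for i in range(config.n_per_group):
            subject_seed = i if group == "MDD" else config.n_per_group + i
            for condition in conditions:
                yield generate_coupled_recording(config, group, condition, subject_seed)


def generate_cohort(config: SimulationConfig, conditions=None) -> list[LabeledRecording]:
    """Materialized cohort: n_per_group x |groups| x |conditions| recordings."""
    return list(iter_cohort(config, conditions))


# ---------------------------------------------------------------------------
# Default coupling: effect directions built into the cohort
#
# Delta coupling is stronger and more widespread in MDD than HC and shrinks
# after the stimulus; beta coupling is weaker in MDD than HC and grows after
# the stimulus. Alpha increases post-stimulus; theta changes mildly.

_FRONTAL = ("Fp1", "Fp2", "Fpz", "F3", "F4", "F7", "F8")
_CENTRAL = ("Cz", "C3", "C4")
_TEMPORAL = ("T7", "T8")
_POSTERIOR = ("Pz", "P3", "P4", "P7", "P8", "O1", "O2")


def default_band_coupling() -> dict:
    """Coupling table keyed by (group, condition, band name)."""
    delta, theta = BAND_BY_NAME["delta"], BAND_BY_NAME["theta"]
    alpha, beta = BAND_BY_NAME["alpha"], BAND_BY_NAME["beta"]

    def spec(band, strength, channels):
        return CouplingSpec(band, strength, _pairs(channels))

    mdd = {
        "pre": {
            "delta": spec(delta, 0.985, _FRONTAL + _CENTRAL + ("Pz", "P3")),
            "theta": spec(theta, 0.950, ("Pz", "P3", "P4", "O1", "O2")),
            "alpha": spec(alpha, 0.950, _POSTERIOR),
            "beta": spec(beta, 0.945, _CENTRAL + _TEMPORAL),
        },
        "post": {
            "delta": spec(delta, 0.960, _FRONTAL + ("Cz", "C3")),
            "theta": spec(theta, 0.955, ("Pz", "P3", "P4", "O1", "O2")),
            "alpha": spec(alpha, 0.965, _POSTERIOR),
            "beta": spec(beta, 0.960, _CENTRAL + _TEMPORAL + ("F3", "F4")),
        },
    }
    mdd["music"] = mdd["post"]
    hc_by_band = {
        "delta": spec(delta, 0.945, ("Fp1", "Fp2", "Fpz", "F3", "F4")),
        "theta": spec(theta, 0.960, _POSTERIOR),
        "alpha": spec(alpha, 0.965, _POSTERIOR + ("Cz",)),
        "beta": spec(beta, 0.985, _CENTRAL + _TEMPORAL
                     + ("F3", "F4", "Pz", "P3", "P4", "Fpz")),
    }
    table = {}
    for condition, by_band in mdd.items():
        for band_name, s in by_band.items():
            table[("MDD", condition, band_name)] = s
    for condition in CONDITIONS:
        for band_name, s in hc_by_band.items():
            table[("HC", condition, band_name)] = s
    return table


# ---------------------------------------------------------------------------
# On-disk cohorts: one CSV per (subject, condition) plus a JSON manifest.

def write_cohort(recordings, outdir) -> str:
    """Write a cohort as CSV matrices plus ``cohort_manifest.json``.

    Returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording_csv(os.path.join(outdir, fname), rec.recording)
        entries.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "condition": rec.condition,
            "file": fname,
            "sampling_rate": rec.recording.sampling_rate,
            "seed": rec.recording.meta.get("subject_seed"),
        })
    manifest_path = os.path.join(outdir, "cohort_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"recordings": entries}, fh, indent=1, sort_keys=True)
    return manifest_path


def read_cohort(indir):
    """Yield LabeledRecording objects from a written cohort directory."""
    with open(os.path.join(indir, "cohort_manifest.json")) as fh:
        manifest = json.load(fh)
    for entry in manifest["recordings"]:
        rec = read_recording_csv(
            os.path.join(indir, entry["file"]), entry["sampling_rate"],
            meta={"group": entry["group"], "condition": entry["condition"]},
        )
        yield LabeledRecording(rec, entry["subject_id"], entry["group"],
                               entry["condition"])
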
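"""Seeded synthetic two-group EEG cohorts with known ground truth.

The study data this package analyses (14-channel consumer-headset EEG of
an experimental ADHD group and a control group across four time events)
are not publicly available, so this module generates surrogate cohorts
whose statistical structure is fully known and configurable:

* four contiguous time events per recording — eyes-open baseline (1),
  eyes-closed baseline (2), a 3-minute virtual lecture (3) and 5 minutes
  of gameplay (4);
* per (group, event, electrode, band) oscillatory amplitude, synthesized
  as band-pass-filtered white noise scaled to a target RMS so spectra
  look realistic rather than line-like;
* an eyes-closed occipital alpha enhancement in event 2 (classic alpha
  blocking in reverse), and an experimental-group frontal/prefrontal
  beta boost during events 3-4 at AF4, F4, F8 and FC6 — the qualitative
  group effect the analysis chain is meant to recover;
* 1/f background noise, transient high-amplitude movement bursts, and
  contact-quality dropouts mirrored in per-channel CQ/EQ series.

Everything is a pure function of the spec plus seed, so cohorts are
exactly reproducible. Ground truth (realized amplitudes, artifact and
dropout intervals) is returned alongside each recording.

A companion generator produces 7-point Likert survey tables from
per-question categorical response profiles.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition, validate_bands
from .errors import ParameterError
from .montage import CHANNELS, Montage

__all__ = [
    "EVENT_NAMES",
    "CohortSpec",
    "EEGRecording",
    "GroundTruth",
    "CohortMember",
    "generate_recording",
    "generate_cohort",
    "inject_quality_dropout",
    "generate_survey",
]

EVENT_NAMES = {1: "eyes_open", 2: "eyes_closed", 3: "lecture", 4: "play"}

GROUPS = ("experimental", "control")

#: Baseline oscillation RMS per band (µV), a plausible resting profile.
DEFAULT_AMPLITUDES = {
    "theta": 4.0,
    "alpha": 5.0,
    "betaL": 2.5,
    "betaH": 2.0,
    "gamma": 1.2,
}

OCCIPITAL = ("O1", "O2")
FRONTAL_BOOST_SITES = ("AF4", "F4", "F8", "FC6")


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults emulate the study conditions.

    Cohort sizes default to the 9 experimental / 6 control participants
    retained after quality screening in the study. Durations are 60 s for
    each baseline (not reported; a conventional choice), 180 s for the
    lecture and 300 s for gameplay. ``boost_factor`` multiplies the RMS
    amplitude of ``boost_bands`` at ``boost_channels`` for the
    experimental group during ``boost_events``; it is ground truth to be
    recovered, not a claim about effect size in real data.
    """

    n_experimental: int = 9
    n_control: int = 6
    sampling_rate: float = 128.0
    event_durations: tuple = (60.0, 60.0, 180.0, 300.0)
    base_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    amplitude_overrides: Mapping = field(default_factory=dict)
    occipital_alpha_factor: float = 2.0
    boost_channels: tuple = FRONTAL_BOOST_SITES
    boost_bands: tuple = ("betaH",)
    boost_factor: float = 1.5
    boost_events: tuple = (3, 4)
    noise_rms: float = 3.0
    noise_exponent: float = 1.0
    artifact_rate: float = 1.0  # movement bursts per minute
    artifact_amplitude: float = 300.0  # µV peak
    artifact_duration: float = 0.5  # s
    dropout_rate: float = 0.0  # fraction of recording time degraded
    quality_rate: float = 1.0  # Hz of the CQ/EQ series
    bands: tuple = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experimental < 0 or self.n_control < 0:
            raise ParameterError("cohort sizes must be >= 0")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if len(self.event_durations) != 4 or any(d <= 0 for d in self.event_durations):
            raise ParameterError("event_durations must be 4 positive durations (s)")
        if any(a < 0 for a in self.base_amplitudes.values()):
            raise ParameterError("amplitudes must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.occipital_alpha_factor <= 0 or self.boost_factor <= 0:
            raise ParameterError("amplitude factors must be > 0")
        validate_bands(self.bands)

    def amplitude(self, group: str, event: int, channel: str, band: str) -> float:
        """Resolve the target RMS for one (group, event, channel, band)."""
        value = float(self.base_amplitudes.get(band, 0.0))
        if band == "alpha" and event == 2 and channel in OCCIPITAL:
            value *= self.occipital_alpha_factor
        if (
            group == "experimental"
            and event in self.boost_events
            and channel in self.boost_channels
            and band in self.boost_bands
        ):
            value *= self.boost_factor
        for key, override in self.amplitude_overrides.items():
            g, e, c, b = key
            if (
                (g is None or g == group)
                and (e is None or e == event)
                and (c is None or c == channel)
                and (b is None or b == band)
            ):
                value = float(override)
        return value


@dataclass
class EEGRecording:
    """A multichannel recording with quality series and event markers.

    ``data`` is a 14 × n-samples voltage matrix in µV, row order given by
    ``montage.labels``. ``cq``/``eq`` are per-channel contact-quality and
    EEG-quality percent series sampled at ``quality_rate`` Hz. ``events``
    maps event id (1-4) to ``(onset_sample, n_samples)``; events are
    contiguous and ordered.
    """

    data: np.ndarray
    sampling_rate: float
    montage: Montage
    cq: np.ndarray
    eq: np.ndarray
    events: dict
    quality_rate: float = 1.0
    participant: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 14:
            raise ParameterError(f"data must be 14 x n_samples, got {self.data.shape}")
        for name in ("cq", "eq"):
            q = np.asarray(getattr(self, name), dtype=float)
            if q.shape[0] != 14:
                raise ParameterError(f"{name} must have 14 rows")
            if q.size and (q.min() < 0.0 or q.max() > 100.0):
                raise ParameterError(f"{name} values must lie in [0, 100]")
            setattr(self, name, q)
        last_end = 0
        for event_id in sorted(self.events):
            onset, length = self.events[event_id]
            if onset < last_end:
                raise ParameterError("event intervals must be ordered and non-overlapping")
            last_end = onset + length

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def event_slice(self, event_id: int) -> slice:
        onset, length = self.events[event_id]
        return slice(onset, onset + length)

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            montage=self.montage,
            cq=self.cq.copy(),
            eq=self.eq.copy(),
            events={k: tuple(v) for k, v in self.events.items()},
            quality_rate=self.quality_rate,
            participant=self.participant,
            group=self.group,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Realized generator parameters for one recording.

    ``amplitudes[event][channel][band]`` gives the configured RMS (µV);
    ``artifacts`` and ``dropouts`` list ``(channel, start_s, end_s)``
    intervals in recording time.
    """

    amplitudes: dict
    artifacts: tuple
    dropouts: tuple


@dataclass(frozen=True)
class CohortMember:
    recording: EEGRecording
    ground_truth: GroundTruth
    group: str


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float, rms: float
) -> np.ndarray:
    """White noise confined to [low, high) Hz, scaled to a target RMS."""
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < low) | (freqs >= high)] = 0.0
    signal = np.fft.irfft(spectrum, n)
    std = signal.std()
    if std == 0.0:
        return np.zeros(n)
    return signal * (rms / std)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent background noise scaled to a target RMS."""
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    signal = np.fft.irfft(spectrum * shaping, n)
    std = signal.std()
    if std == 0.0:
        return np.zeros(n)
    return signal * (rms / std)


def _event_layout(spec: CohortSpec) -> dict:
    fs = spec.sampling_rate
    events, onset = {}, 0
    for event_id, duration in zip((1, 2, 3, 4), spec.event_durations):
        length = int(round(duration * fs))
        events[event_id] = (onset, length)
        onset += length
    return events


def generate_recording(
    spec: CohortSpec, group: str, participant_seed: int, participant: str = ""
) -> tuple:
    """Synthesize one participant's recording and its ground truth.

    The signal per channel is the sum over bands of band-limited
    oscillations at the configured RMS, plus 1/f noise, plus any movement
    bursts; CQ/EQ series sit near 100% except inside dropout intervals.
    Deterministic given ``spec`` and ``participant_seed``.
    """
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(participant_seed)
    fs = spec.sampling_rate
    events = _event_layout(spec)
    n_total = sum(length for _, length in events.values())
    data = np.zeros((14, n_total))
    amplitudes: dict = {}

    for event_id, (onset, length) in events.items():
        amplitudes[event_id] = {}
        for ci, channel in enumerate(CHANNELS):
            amplitudes[event_id][channel] = {}
            for band in spec.bands:
                rms = spec.amplitude(group, event_id, channel, band.name)
                amplitudes[event_id][channel][band.name] = rms
                if rms > 0.0:
                    data[ci, onset : onset + length] += _band_limited_noise(
                        rng, length, fs, band.low, band.high, rms
                    )

    if spec.noise_rms > 0.0:
        for ci in range(14):
            data[ci] += _pink_noise(rng, n_total, fs, spec.noise_exponent, spec.noise_rms)

    # transient high-amplitude movement bursts
    artifacts = []
    total_minutes = n_total / fs / 60.0
    n_bursts = rng.poisson(spec.artifact_rate * total_minutes) if spec.artifact_rate > 0 else 0
    burst_len = max(int(round(spec.artifact_duration * fs)), 2)
    for _ in range(n_bursts):
        ci = int(rng.integers(0, 14))
        start = int(rng.integers(0, max(n_total - burst_len, 1)))
        t = np.arange(burst_len) / fs
        burst = (
            spec.artifact_amplitude
            * np.hanning(burst_len)
            * np.sin(2.0 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))
        )
        data[ci, start : start + burst_len] += burst
        artifacts.append((CHANNELS[ci], start / fs, (start + burst_len) / fs))

    # CQ/EQ percent series near 100 with a small noise floor
    n_quality = int(np.ceil(n_total / fs * spec.quality_rate))
    cq = np.clip(100.0 - rng.exponential(1.5, size=(14, n_quality)), 0.0, 100.0)
    eq = np.clip(100.0 - rng.exponential(1.5, size=(14, n_quality)), 0.0, 100.0)

    recording = EEGRecording(
        data=data,
        sampling_rate=fs,
        montage=Montage(),
        cq=cq,
        eq=eq,
        events=events,
        quality_rate=spec.quality_rate,
        participant=participant,
        group=group,
    )

    # seeded contact dropouts (step drift + low quality)
    dropouts = []
    if spec.dropout_rate > 0.0:
        total_s = n_total / fs
        drop_len = 5.0
        n_drops = max(int(round(spec.dropout_rate * total_s / drop_len)), 1)
        for _ in range(n_drops):
            channel = CHANNELS[int(rng.integers(0, 14))]
            start = float(rng.uniform(0.0, total_s - drop_len))
            recording = inject_quality_dropout(recording, channel, (start, start + drop_len))
            dropouts.append((channel, start, start + drop_len))

    truth = GroundTruth(
        amplitudes=amplitudes, artifacts=tuple(artifacts), dropouts=tuple(dropouts)
    )
    return recording, truth


def generate_cohort(spec: CohortSpec) -> list:
    """Generate the full two-group cohort from the master seed.

    Per-participant seeds are spawned from ``spec.seed`` via a seed
    sequence, so any two cohorts built from the same spec are identical
    and participants are mutually independent.
    """
    n_total = spec.n_experimental + spec.n_control
    if n_total < 2:
        raise ParameterError("need at least 2 participants in total")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_total, dtype=np.uint32)
    members = []
    for i in range(n_total):
        if i < spec.n_experimental:
            group, label = "experimental", f"E{i + 1:02d}"
        else:
            group, label = "control", f"C{i - spec.n_experimental + 1:02d}"
        recording, truth = generate_recording(spec, group, int(seeds[i]), participant=label)
        members.append(CohortMember(recording=recording, ground_truth=truth, group=group))
    return members


def inject_quality_dropout(
    recording: EEGRecording, channel: str, interval: tuple
) -> EEGRecording:
    """Return a copy with a contact dropout on one channel.

    Inside ``interval`` (seconds) the channel's CQ/EQ are forced to 10%
    and the voltage trace is replaced by a high-amplitude step drift; the
    original recording is untouched and all other channels (and all
    samples outside the interval) are bit-identical.
    """
    start_s, end_s = float(interval[0]), float(interval[1])
    if start_s < 0.0 or end_s > recording.duration + 1e-9 or start_s > end_s:
        raise ParameterError(
            f"interval {interval} outside recording of {recording.duration:.1f} s"
        )
    out = recording.copy()
    if end_s <= start_s:
        return out
    ci = recording.montage.index(channel)
    fs = recording.sampling_rate
    i0, i1 = int(round(start_s * fs)), min(int(round(end_s * fs)), recording.n_samples)
    n = i1 - i0
    if n > 0:
        ramp = np.linspace(0.0, 1.0, n)
        out.data[ci, i0:i1] = 500.0 + 300.0 * ramp  # step offset + slow drift, µV
    q0 = int(np.floor(start_s * recording.quality_rate))
    q1 = min(int(np.ceil(end_s * recording.quality_rate)), out.cq.shape[1])
    out.cq[ci, q0:q1] = 10.0
    out.eq[ci, q0:q1] = 10.0
    return out


def generate_survey(
    group_profiles: Mapping[str, Mapping[str, Sequence[float]]],
    n_per_group: Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Draw a synthetic 7-point Likert response table.

    ``group_profiles[group][question]`` is a length-7 probability vector
    over responses 1-7. Returns one row per participant with ``group``
    and one integer column per question id.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(group_profiles):
        profile = group_profiles[group]
        for question, probs in profile.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (7,) or probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    f"profile for {group}/{question} must be 7 probabilities summing to 1"
                )
        for i in range(int(n_per_group[group])):
            row = {"participant": f"{group[:1].upper()}{i + 1:03d}", "group": group}
            for question in profile:
                probs = np.asarray(profile[question], dtype=float)
                row[question] = int(rng.choice(np.arange(1, 8), p=probs))
            rows.append(row)
    return pd.DataFrame(rows)
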
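"""From recordings to band-power tables and cognitive-state indices.

This module implements the quantitative EEG chain: participant-level
quality screening on the vendor-style CQ/EQ percent series, automatic
epoch rejection on peak-to-peak amplitude, five-band absolute power per
electrode via a windowed FFT periodogram, transparent band-ratio proxies
for the vendor's proprietary performance metrics (attention, engagement,
excitement, stress, relaxation, interest), missing-value interpolation
and group-level time-course aggregation.

Performance-metric proxies
--------------------------
The consumer platform does not disclose its performance-metric formulas,
so this package defines documented replacements built from classical
band-ratio indices. Per epoch, with band powers summed over the named
electrode sets:

====================  ====================================================
attention             frontal (AF3, AF4, F3, F4) (βL+βH) / (θ+α)
engagement            all-channel (βL+βH) / (α+θ)
excitement            frontal (βH+γ) / total
stress                right-vs-left frontal alpha asymmetry (R−L)/(R+L),
                      R = {AF4, F4}, L = {AF3, F3}
relaxation            occipital (O1, O2) α / total
interest              frontal alpha asymmetry (F4−F3)/(F4+F3)
====================  ====================================================

Each raw index is standardized against the participant's baseline
(events 1-2) mean and SD and squashed to [0, 1] by the logistic
function, so an epoch at baseline level maps to 0.5. These are declared
proxies, not reconstructions of the vendor's values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition, validate_bands
from .errors import (
    BaselineError,
    EventNotFoundError,
    ParameterError,
    QualityError,
    ResolutionError,
    SampleError,
)
from .montage import CHANNELS
from .synth_eeg import CohortMember, EEGRecording

__all__ = [
    "PM_METRICS",
    "quality_filter",
    "EpochSet",
    "reject_epochs",
    "band_power",
    "epoch_band_powers",
    "band_power_table",
    "BaselineStats",
    "baseline_stats",
    "performance_metrics",
    "cohort_pm_series",
    "interpolate_missing",
    "interpolate_pm",
    "aggregate_timecourse",
]

PM_METRICS = ("attention", "engagement", "excitement", "stress", "relaxation", "interest")

FRONTAL = ("AF3", "AF4", "F3", "F4")
RIGHT_FRONTAL = ("AF4", "F4")
LEFT_FRONTAL = ("AF3", "F3")
OCCIPITAL = ("O1", "O2")


def _as_recording(item) -> EEGRecording:
    return item.recording if isinstance(item, CohortMember) else item


# ---------------------------------------------------------------------------
# quality screening
# ---------------------------------------------------------------------------

def quality_filter(
    recordings: Sequence,
    threshold: float = 70.0,
    coverage: float = 1.0,
    events: Sequence[int] = (1, 2, 3, 4),
):
    """Screen participants on contact/EEG quality.

    A recording is kept only if, within every analysed event, the
    fraction of (channel, time) quality samples with both CQ ≥
    ``threshold`` and EQ ≥ ``threshold`` reaches ``coverage`` (default
    1.0, i.e. consistently good contact; the threshold comparison is
    inclusive). Accepts recordings or cohort members.

    Returns ``(kept, excluded, report)`` where the report lists one row
    per participant with the worst per-event coverage and a reason.
    """
    if not 0.0 < threshold <= 100.0:
        raise ParameterError(f"threshold must be in (0, 100], got {threshold}")
    if not 0.0 < coverage <= 1.0:
        raise ParameterError(f"coverage must be in (0, 1], got {coverage}")
    kept, excluded, rows = [], [], []
    for item in recordings:
        rec = _as_recording(item)
        if rec.cq.size == 0 or rec.eq.size == 0:
            raise QualityError(
                f"recording {rec.participant!r} lacks CQ/EQ quality series"
            )
        worst = 1.0
        for event_id in events:
            if event_id not in rec.events:
                raise EventNotFoundError(f"event {event_id} missing in {rec.participant!r}")
            onset, length = rec.events[event_id]
            q0 = int(np.floor(onset / rec.sampling_rate * rec.quality_rate))
            q1 = int(np.ceil((onset + length) / rec.sampling_rate * rec.quality_rate))
            q1 = min(q1, rec.cq.shape[1])
            good = (rec.cq[:, q0:q1] >= threshold) & (rec.eq[:, q0:q1] >= threshold)
            worst = min(worst, float(good.mean()))
        ok = worst >= coverage
        (kept if ok else excluded).append(item)
        rows.append(
            {
                "participant": rec.participant,
                "group": rec.group,
                "kept": ok,
                "min_event_coverage": worst,
                "reason": "" if ok else f"quality coverage {worst:.3f} < {coverage:.3f}",
            }
        )
    return kept, excluded, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# epoching and band power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochSet:
    """Non-overlapping epochs of one event after artifact rejection.

    ``data`` holds the accepted epochs (n_accepted, 14, n_samples);
    ``accepted`` flags all ``n_total`` epoch slots in temporal order;
    ``onsets`` are epoch onsets in seconds relative to event start.
    """

    data: np.ndarray
    accepted: np.ndarray
    onsets: np.ndarray
    epoch_length: float

    @property
    def n_total(self) -> int:
        return self.accepted.size


def reject_epochs(
    recording: EEGRecording,
    event: int,
    epoch_length: float = 2.0,
    amplitude_limit: float = 100.0,
) -> EpochSet:
    """Segment an event into epochs and drop high-amplitude ones.

    An epoch is rejected when any channel's peak-to-peak amplitude
    exceeds ``amplitude_limit`` (µV); temporal order is preserved and a
    trailing partial epoch is discarded.
    """
    if event not in recording.events:
        raise EventNotFoundError(f"event {event} not marked in recording")
    fs = recording.sampling_rate
    n_per = int(round(epoch_length * fs))
    if n_per < 2:
        raise ParameterError("epoch_length must span at least 2 samples")
    seg = recording.data[:, recording.event_slice(event)]
    n_epochs = seg.shape[1] // n_per
    if n_epochs == 0:
        raise ParameterError(
            f"event {event} shorter ({seg.shape[1] / fs:.2f} s) than one epoch"
        )
    epochs = seg[:, : n_epochs * n_per].reshape(14, n_epochs, n_per).transpose(1, 0, 2)
    ptp = epochs.max(axis=2) - epochs.min(axis=2)
    accepted = ~(ptp > amplitude_limit).any(axis=1)
    onsets = np.arange(n_epochs) * epoch_length
    return EpochSet(
        data=epochs[accepted],
        accepted=accepted,
        onsets=onsets,
        epoch_length=epoch_length,
    )


def band_power(
    epoch: np.ndarray, sampling_rate: float, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> np.ndarray:
    """Absolute band power per channel (µV²) from a Hann periodogram.

    The mean is removed before the FFT, so results are invariant to DC
    offsets (and to sign flips, by symmetry). Power in band ``[low,
    high)`` is the integral of the periodogram over bins with frequency
    in that half-open range; the five default bands therefore partition
    the total 4-45 Hz power exactly.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    bands = validate_bands(bands)
    min_width = min(band.width for band in bands)
    if epoch.shape[1] / sampling_rate < 2.0 / min_width - 1e-12:
        raise ResolutionError(
            f"epoch of {epoch.shape[1] / sampling_rate:.3f} s cannot resolve a "
            f"{min_width:.1f} Hz band; need >= {2.0 / min_width:.3f} s"
        )
    freqs, psd = sps.periodogram(
        epoch, fs=sampling_rate, window="hann", detrend="constant", axis=-1
    )
    df = freqs[1] - freqs[0]
    out = np.empty((epoch.shape[0], len(bands)))
    for bi, band in enumerate(bands):
        mask = (freqs >= band.low) & (freqs < band.high)
        out[:, bi] = psd[:, mask].sum(axis=-1) * df
    return out


def epoch_band_powers(
    recording: EEGRecording,
    event: int,
    epoch_length: float = 2.0,
    amplitude_limit: float = 100.0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> tuple:
    """Per-epoch band powers for one event.

    Returns ``(powers, epochs)`` where ``powers`` has shape
    (n_total_epochs, 14, n_bands) with NaN rows for rejected epochs.
    """
    epochs = reject_epochs(recording, event, epoch_length, amplitude_limit)
    powers = np.full((epochs.n_total, 14, len(tuple(bands))), np.nan)
    if epochs.data.shape[0]:
        stacked = band_power(
            epochs.data.reshape(-1, epochs.data.shape[2]), recording.sampling_rate, bands
        ).reshape(epochs.data.shape[0], 14, -1)
        powers[epochs.accepted] = stacked
    return powers, epochs


def band_power_table(
    members: Sequence,
    events: Sequence[int] = (3, 4),
    epoch_length: float = 2.0,
    amplitude_limit: float = 100.0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Tidy participant × event × electrode × band mean absolute power.

    Epoch-mean power over accepted epochs; rows keyed by participant,
    group, event, electrode and band.
    """
    bands = tuple(bands)
    rows = []
    for item in members:
        rec = _as_recording(item)
        for event in events:
            powers, _ = epoch_band_powers(rec, event, epoch_length, amplitude_limit, bands)
            with np.errstate(invalid="ignore"):
                mean_power = np.nanmean(powers, axis=0)  # (14, n_bands)
            for ci, channel in enumerate(rec.montage.labels):
                for bi, band in enumerate(bands):
                    rows.append(
                        {
                            "participant": rec.participant,
                            "group": rec.group,
                            "event": event,
                            "electrode": channel,
                            "band": band.name,
                            "power": mean_power[ci, bi],
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# performance-metric proxies
# ---------------------------------------------------------------------------

def _channel_indices(labels: Sequence[str]) -> list:
    return [CHANNELS.index(lb) for lb in labels]

_FRONTAL_IX = _channel_indices(FRONTAL)
_RIGHT_IX = _channel_indices(RIGHT_FRONTAL)
_LEFT_IX = _channel_indices(LEFT_FRONTAL)
_OCC_IX = _channel_indices(OCCIPITAL)
_F4_IX = CHANNELS.index("F4")
_F3_IX = CHANNELS.index("F3")


def _raw_indices(powers: np.ndarray, band_names: Sequence[str]) -> dict:
    """Raw (unstandardized) metric indices from (n_epochs, 14, n_bands)."""
    ix = {name: band_names.index(name) for name in BAND_NAMES}
    theta = powers[:, :, ix["theta"]]
    alpha = powers[:, :, ix["alpha"]]
    beta = powers[:, :, ix["betaL"]] + powers[:, :, ix["betaH"]]
    betah = powers[:, :, ix["betaH"]]
    gamma = powers[:, :, ix["gamma"]]
    total = powers.sum(axis=2)

    def s(arr, sel):
        return arr[:, sel].sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_r, alpha_l = s(alpha, _RIGHT_IX), s(alpha, _LEFT_IX)
        a4, a3 = alpha[:, _F4_IX], alpha[:, _F3_IX]
        raw = {
            "attention": s(beta, _FRONTAL_IX) / (s(theta, _FRONTAL_IX) + s(alpha, _FRONTAL_IX)),
            "engagement": beta.sum(axis=1) / (alpha.sum(axis=1) + theta.sum(axis=1)),
            "excitement": (s(betah, _FRONTAL_IX) + s(gamma, _FRONTAL_IX)) / s(total, _FRONTAL_IX),
            "stress": (alpha_r - alpha_l) / (alpha_r + alpha_l),
            "relaxation": s(alpha, _OCC_IX) / s(total, _OCC_IX),
            "interest": (a4 - a3) / (a4 + a3),
        }
    return raw


@dataclass(frozen=True)
class BaselineStats:
    """Per-metric baseline mean and SD from the calibration events."""

    mean: dict
    sd: dict
    n_epochs: int


def baseline_stats(
    recording: EEGRecording,
    baseline_events: Sequence[int] = (1, 2),
    epoch_length: float = 1.0,
    amplitude_limit: float = 100.0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> BaselineStats:
    """Baseline mean/SD of each raw metric index over events 1-2."""
    bands = tuple(bands)
    band_names = [b.name for b in bands]
    chunks = []
    for event in baseline_events:
        powers, _ = epoch_band_powers(recording, event, epoch_length, amplitude_limit, bands)
        chunks.append(powers)
    powers = np.concatenate(chunks, axis=0)
    ok = ~np.isnan(powers[:, 0, 0])
    if not ok.any():
        raise BaselineError("no accepted baseline epochs; cannot standardize metrics")
    raw = _raw_indices(powers[ok], band_names)
    mean = {m: float(np.nanmean(v)) for m, v in raw.items()}
    sd = {m: float(np.nanstd(v)) for m, v in raw.items()}
    return BaselineStats(mean=mean, sd=sd, n_epochs=int(ok.sum()))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def performance_metrics(
    recording: EEGRecording,
    event: int,
    baseline: BaselineStats,
    epoch_length: float = 1.0,
    amplitude_limit: float = 100.0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-epoch [0, 1] performance-metric series for one event.

    Raw indices are standardized against the baseline statistics and
    mapped through the logistic function; a zero baseline SD falls back
    to 1 so a baseline-level epoch still maps to 0.5. Rejected epochs
    yield missing values.
    """
    if baseline is None:
        raise BaselineError("baseline statistics are required")
    bands = tuple(bands)
    powers, epochs = epoch_band_powers(recording, event, epoch_length, amplitude_limit, bands)
    raw = _raw_indices(powers, [b.name for b in bands])
    out = pd.DataFrame(
        {
            "participant": recording.participant,
            "group": recording.group,
            "event": event,
            "time": epochs.onsets,
        }
    )
    for metric in PM_METRICS:
        sd = baseline.sd[metric] if baseline.sd[metric] > 0 else 1.0
        out[metric] = _logistic((raw[metric] - baseline.mean[metric]) / sd)
    return out


def cohort_pm_series(
    members: Sequence,
    events: Sequence[int] = (3, 4),
    baseline_events: Sequence[int] = (1, 2),
    epoch_length: float = 1.0,
    amplitude_limit: float = 100.0,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Concatenated PM series for a whole cohort (tidy, one row/epoch)."""
    frames = []
    for item in members:
        rec = _as_recording(item)
        stats = baseline_stats(rec, baseline_events, epoch_length, amplitude_limit, bands)
        for event in events:
            frames.append(
                performance_metrics(rec, event, stats, epoch_length, amplitude_limit, bands)
            )
    if not frames:
        raise SampleError("empty cohort")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# missing values and aggregation
# ---------------------------------------------------------------------------

def interpolate_missing(values: Sequence[float]) -> np.ndarray:
    """Fill gaps in a metric series.

    Interior gaps are linearly interpolated between flanking observed
    values; leading/trailing gaps are held at the nearest observation.
    Observed values are returned unchanged.
    """
    series = pd.Series(np.asarray(values, dtype=float))
    if series.isna().all():
        raise SampleError("cannot interpolate an all-missing series")
    filled = series.interpolate(method="linear", limit_direction="both")
    return filled.to_numpy()


def interpolate_pm(pm: pd.DataFrame, metrics: Sequence[str] = PM_METRICS) -> pd.DataFrame:
    """Apply :func:`interpolate_missing` per participant × event column."""
    out = pm.copy()
    for (_, _), idx in out.groupby(["participant", "event"]).groups.items():
        for metric in metrics:
            values = out.loc[idx, metric]
            if values.isna().all():
                continue  # left missing; reported downstream
            out.loc[idx, metric] = interpolate_missing(values.to_numpy())
    return out


def aggregate_timecourse(pm: pd.DataFrame, metric: str, event: int) -> pd.DataFrame:
    """Per-second group mean ± SD curve for one metric and event.

    Series are already aligned to event onset (the ``time`` column);
    population SD (ddof 0) so a single participant yields SD 0. ``n``
    counts non-missing participants per time bin.
    """
    if metric not in PM_METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    sub = pm[pm["event"] == event]
    if sub.empty:
        raise SampleError(f"no PM rows for event {event}")
    grouped = sub.groupby(["time", "group"])[metric]
    out = grouped.agg(
        mean="mean", sd=lambda v: float(np.std(v.dropna())) if v.notna().any() else np.nan,
        n="count",
    ).reset_index()
    if (out.groupby("group")["n"].max() == 0).any():
        raise SampleError("a group has no observed values")
    return out.sort_values(["time", "group"], ignore_index=True)
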
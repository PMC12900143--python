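"""Feature-chain tests: quality gate, epoching, band power, PM proxies."""

import numpy as np
import pandas as pd
import pytest

from vreeg.bands import DEFAULT_BANDS
from vreeg.errors import (
    BaselineError,
    EventNotFoundError,
    QualityError,
    ResolutionError,
    SampleError,
)
from vreeg.eeg_features import (
    PM_METRICS,
    aggregate_timecourse,
    band_power,
    baseline_stats,
    cohort_pm_series,
    epoch_band_powers,
    interpolate_missing,
    performance_metrics,
    quality_filter,
    reject_epochs,
)
from vreeg.montage import CHANNELS
from vreeg.synth_eeg import CohortSpec, generate_cohort, generate_recording, inject_quality_dropout

FS = 128.0


def sinusoid_epoch(freq, seconds=2.0, fs=FS, amplitude=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(amplitude * np.sin(2 * np.pi * freq * t), (14, 1))


class TestQualityFilter:
    def test_perfect_quality_all_kept(self, small_cohort):
        kept, excluded, report = quality_filter(small_cohort, threshold=70.0)
        assert len(kept) == len(small_cohort)
        assert not excluded
        assert report["kept"].all()

    def test_full_dropout_participant_excluded(self, small_cohort):
        doctored = list(small_cohort)
        victim = doctored[1]
        rec = inject_quality_dropout(
            victim.recording, "T7", (0.0, victim.recording.duration)
        )
        doctored[1] = type(victim)(recording=rec, ground_truth=victim.ground_truth,
                                   group=victim.group)
        kept, excluded, report = quality_filter(doctored, threshold=70.0)
        assert len(excluded) == 1
        assert excluded[0].recording.participant == victim.recording.participant
        reasons = report.loc[~report["kept"], "reason"]
        assert reasons.str.contains("coverage").all()

    def test_boundary_exactly_at_threshold_kept(self, small_cohort):
        rec = small_cohort[0].recording.copy()
        rec.cq[:] = 70.0
        rec.eq[:] = 70.0
        kept, excluded, _ = quality_filter([rec], threshold=70.0)
        assert kept and not excluded

    def test_missing_quality_series_is_hard_error(self, small_cohort):
        rec = small_cohort[0].recording.copy()
        rec.cq = np.zeros((14, 0))
        rec.eq = np.zeros((14, 0))
        with pytest.raises(QualityError):
            quality_filter([rec])


class TestRejectEpochs:
    def test_clean_signal_no_rejections(self, small_cohort):
        rec = small_cohort[0].recording
        epochs = reject_epochs(rec, 1, epoch_length=2.0, amplitude_limit=1000.0)
        assert epochs.accepted.all()

    def test_injected_burst_rejects_exactly_that_epoch(self, clean_spec):
        rec, _ = generate_recording(clean_spec, "control", 3)
        rec = rec.copy()
        fs = int(rec.sampling_rate)
        onset, _ = rec.events[3]
        rec.data[4, onset + 2 * fs + 10 : onset + 2 * fs + 40] += 500.0  # in epoch 1
        epochs = reject_epochs(rec, 3, epoch_length=2.0, amplitude_limit=100.0)
        rejected = np.flatnonzero(~epochs.accepted)
        assert list(rejected) == [1]

    def test_zero_limit_rejects_everything(self, small_cohort):
        rec = small_cohort[0].recording
        epochs = reject_epochs(rec, 2, epoch_length=2.0, amplitude_limit=0.0)
        assert not epochs.accepted.any()

    def test_missing_event_raises(self, small_cohort):
        with pytest.raises(EventNotFoundError):
            reject_epochs(small_cohort[0].recording, 9)


class TestBandPower:
    @pytest.mark.parametrize(
        "freq, band",
        [(6.0, "theta"), (10.0, "alpha"), (14.0, "betaL"), (20.0, "betaH"), (35.0, "gamma")],
    )
    def test_sinusoid_lands_in_its_band(self, freq, band):
        powers = band_power(sinusoid_epoch(freq), FS)
        names = [b.name for b in DEFAULT_BANDS]
        fraction = powers[0, names.index(band)] / powers[0].sum()
        assert fraction >= 0.95

    def test_zero_epoch_zero_power(self):
        powers = band_power(np.zeros((14, 256)), FS)
        assert np.all(powers == 0.0)

    def test_partition_closure(self):
        rng = np.random.default_rng(5)
        epoch = rng.standard_normal((14, 512))
        powers = band_power(epoch, FS)
        freqs = np.fft.rfftfreq(512, 1 / FS)
        from scipy.signal import periodogram

        f, psd = periodogram(epoch, fs=FS, window="hann", detrend="constant", axis=-1)
        total = psd[:, (f >= 4.0) & (f < 45.0)].sum(axis=-1) * (f[1] - f[0])
        assert np.allclose(powers.sum(axis=1), total, rtol=1e-9)

    def test_dc_and_sign_invariance(self):
        rng = np.random.default_rng(6)
        epoch = rng.standard_normal((14, 256))
        base = band_power(epoch, FS)
        assert np.allclose(band_power(epoch + 37.5, FS), base, rtol=1e-9)
        assert np.allclose(band_power(-epoch, FS), base, rtol=1e-9)

    def test_too_short_epoch_raises(self):
        with pytest.raises(ResolutionError):
            band_power(np.zeros((14, 32)), FS)  # 0.25 s < 0.5 s needed


def tiled_recording(spec_seed=21):
    """A recording whose every 1-s epoch is identical (baseline == signal)."""
    spec = CohortSpec(
        n_experimental=1, n_control=1,
        event_durations=(4.0, 4.0, 4.0, 4.0),
        noise_rms=0.0, artifact_rate=0.0, seed=spec_seed,
    )
    rec, _ = generate_recording(spec, "control", spec_seed)
    rec = rec.copy()
    fs = int(rec.sampling_rate)
    chunk = rec.data[:, :fs]
    rec.data = np.tile(chunk, (1, rec.n_samples // fs))
    return rec


class TestPerformanceMetrics:
    def test_baseline_epoch_maps_to_half(self):
        rec = tiled_recording()
        stats = baseline_stats(rec, epoch_length=1.0)
        pm = performance_metrics(rec, 3, stats, epoch_length=1.0)
        for metric in PM_METRICS:
            assert np.allclose(pm[metric], 0.5)

    def test_doubled_frontal_beta_raises_attention(self):
        spec = CohortSpec(
            n_experimental=1, n_control=1,
            event_durations=(8.0, 8.0, 8.0, 8.0),
            noise_rms=0.0, artifact_rate=0.0,
            amplitude_overrides={(None, 3, None, "betaH"): 4.0,
                                 (None, 3, None, "betaL"): 5.0},
            seed=31,
        )
        rec, _ = generate_recording(spec, "control", 31)
        stats = baseline_stats(rec, epoch_length=1.0)
        pm = performance_metrics(rec, 3, stats, epoch_length=1.0)
        assert pm["attention"].mean() > 0.5

    def test_symmetric_f3_f4_alpha_gives_neutral_interest(self, clean_spec):
        rec, _ = generate_recording(clean_spec, "control", 17)
        rec = rec.copy()
        rec.data[rec.montage.index("F4")] = rec.data[rec.montage.index("F3")]
        stats = baseline_stats(rec, epoch_length=1.0)
        pm = performance_metrics(rec, 4, stats, epoch_length=1.0)
        assert np.allclose(pm["interest"], 0.5)

    def test_metrics_bounded(self, small_cohort):
        pm = cohort_pm_series(small_cohort[:2], events=(3, 4))
        observed = pm[list(PM_METRICS)].to_numpy()
        observed = observed[~np.isnan(observed)]
        assert observed.min() >= 0.0 and observed.max() <= 1.0

    def test_missing_baseline_raises(self, small_cohort):
        with pytest.raises(BaselineError):
            performance_metrics(small_cohort[0].recording, 3, None)

    def test_rejected_epochs_become_missing(self, clean_spec):
        rec, _ = generate_recording(clean_spec, "control", 13)
        rec = rec.copy()
        fs = int(rec.sampling_rate)
        onset, _ = rec.events[4]
        rec.data[0, onset + 3 * fs : onset + 3 * fs + 20] += 900.0
        stats = baseline_stats(rec, epoch_length=1.0)
        pm = performance_metrics(rec, 4, stats, epoch_length=1.0)
        assert pm["attention"].isna().sum() == 1
        assert pm["attention"].isna().iloc[3]

    def test_monotone_attention_in_beta_amplitude(self):
        means = []
        for boost in (1.0, 1.5, 2.0):
            spec = CohortSpec(
                n_experimental=1, n_control=0,
                event_durations=(8.0, 8.0, 8.0, 8.0),
                noise_rms=1.0, artifact_rate=0.0,
                boost_bands=("betaL", "betaH"), boost_factor=boost, seed=41,
            )
            rec, _ = generate_recording(spec, "experimental", 41)
            stats = baseline_stats(rec, epoch_length=1.0)
            pm = performance_metrics(rec, 4, stats, epoch_length=1.0)
            means.append(pm["attention"].mean())
        assert means[0] <= means[1] <= means[2]


class TestInterpolateAndAggregate:
    def test_midpoint_fill(self):
        out = interpolate_missing([0.4, np.nan, 0.6])
        assert np.allclose(out, [0.4, 0.5, 0.6])

    def test_identity_without_missing(self):
        values = [0.2, 0.7, 0.4]
        assert np.allclose(interpolate_missing(values), values)

    def test_edge_hold(self):
        out = interpolate_missing([np.nan, 0.3, 0.3, np.nan])
        assert np.allclose(out, [0.3, 0.3, 0.3, 0.3])

    def test_all_missing_raises(self):
        with pytest.raises(SampleError):
            interpolate_missing([np.nan, np.nan])

    def test_single_participant_aggregate(self):
        pm = pd.DataFrame(
            {
                "participant": "E01", "group": "experimental", "event": 4,
                "time": np.arange(5.0), "attention": [0.4, 0.5, 0.6, 0.5, 0.4],
            }
        )
        curve = aggregate_timecourse(pm, "attention", 4)
        assert np.allclose(curve["mean"], pm["attention"])
        assert np.allclose(curve["sd"], 0.0)
        assert (curve["n"] == 1).all()

    def test_identical_participants_zero_sd(self):
        base = pd.DataFrame(
            {"event": 4, "time": np.arange(4.0), "attention": [0.3, 0.4, 0.5, 0.6]}
        )
        pm = pd.concat(
            [base.assign(participant=p, group="control") for p in ("C01", "C02")],
            ignore_index=True,
        )
        curve = aggregate_timecourse(pm, "attention", 4)
        assert np.allclose(curve["sd"], 0.0)
        assert (curve["n"] == 2).all()

    def test_unknown_metric_raises(self):
        with pytest.raises(KeyError):
            aggregate_timecourse(pd.DataFrame({"event": []}), "focus", 4)
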
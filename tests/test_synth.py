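"""Synthetic study generator: RR truth, ECG rendering, device corruption."""

import numpy as np
import pytest

from hrvagree import (CalibrationError, DeviceErrorModel, RRTruthConfig,
                      StudyDesign, bland_altman, generate_study, mean_hr,
                      render_ecg, rmssd, simulate_device_reading,
                      simulate_rr_series)
from hrvagree.synth import corrupt_beats
from hrvagree.hrv import summarize
from conftest import match_beats


class TestSimulateRRSeries:
    def test_seeded_determinism(self):
        cfg = RRTruthConfig(duration_s=120, seed=5)
        a = simulate_rr_series(cfg)
        b = simulate_rr_series(cfg)
        np.testing.assert_array_equal(a.beat_times_s, b.beat_times_s)

    def test_degenerate_config_gives_metronome(self):
        cfg = RRTruthConfig(duration_s=10, mean_hr_bpm=60,
                            rmssd_target_ms=None, lf_amp_ms=0, hf_amp_ms=0,
                            vlf_drift_ms=0, jitter_sd_ms=0)
        rr = simulate_rr_series(cfg)
        np.testing.assert_allclose(rr.rr_ms, 1000.0)
        assert rmssd(rr) == 0.0

    def test_beats_strictly_increasing_and_span_duration(self, resting_rr):
        assert np.all(np.diff(resting_rr.beat_times_s) > 0)
        assert resting_rr.beat_times_s[0] == 0.0
        assert resting_rr.beat_times_s[-1] == pytest.approx(300.0, abs=2.5)

    def test_rmssd_calibration_over_seeds(self):
        # Monte-Carlo check of the calibration contract: mean realized
        # rMSSD within 10% of target, mean HR within 2%
        target = 50.0
        vals, hrs = [], []
        for seed in range(100):
            rr = simulate_rr_series(RRTruthConfig(
                duration_s=300, mean_hr_bpm=65, rmssd_target_ms=target,
                seed=seed))
            vals.append(rmssd(rr))
            hrs.append(mean_hr(rr))
        assert 45.0 <= np.mean(vals) <= 55.0
        assert abs(np.mean(hrs) - 65.0) / 65.0 < 0.02

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            simulate_rr_series(RRTruthConfig(
                rmssd_target_ms=200.0, lf_amp_ms=0, hf_amp_ms=0,
                vlf_drift_ms=0, jitter_sd_ms=0))

    def test_target_below_lf_floor_raises(self):
        with pytest.raises(CalibrationError):
            simulate_rr_series(RRTruthConfig(
                rmssd_target_ms=1.0, lf_amp_ms=100.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RRTruthConfig(duration_s=-1)
        with pytest.raises(ValueError):
            RRTruthConfig(mean_hr_bpm=20)
        with pytest.raises(ValueError):
            RRTruthConfig(jitter_sd_ms=-1)


class TestRenderEcg:
    def test_metronome_construction(self):
        rr = simulate_rr_series(RRTruthConfig(
            duration_s=10, mean_hr_bpm=60, rmssd_target_ms=None,
            lf_amp_ms=0, hf_amp_ms=0, vlf_drift_ms=0, jitter_sd_ms=0))
        ecg, idx = render_ecg(rr, fs_hz=512)
        assert idx.size == rr.n_beats
        # template centres at exactly 1 s spacing
        np.testing.assert_allclose(np.diff(idx), 512)
        assert ecg.n_samples >= 10 * 512

    def test_clean_peaks_at_beat_indices(self, resting_rr):
        ecg, idx = render_ecg(resting_rr, fs_hz=512, snr_db=np.inf)
        # every template centre is a local maximum of amplitude ~1 mV
        assert np.allclose(ecg.samples[idx], 1.0, atol=0.05)

    def test_low_rate_rejected(self, resting_rr):
        with pytest.raises(ValueError):
            render_ecg(resting_rr, fs_hz=64)

    def test_noise_seed_determinism(self, resting_rr):
        a, _ = render_ecg(resting_rr, snr_db=10, seed=3)
        b, _ = render_ecg(resting_rr, snr_db=10, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSimulateDeviceReading:
    def test_zero_error_model_is_identity(self, resting_rr):
        model = DeviceErrorModel("perfect", epoch_s=300)
        reading = simulate_device_reading(resting_rr, model, seed=0)
        t = resting_rr.beat_times_s
        truth = resting_rr.__class__.from_beat_times(t[t < t[0] + 300.0])
        expected = summarize(truth, epoch_s=300)
        assert reading.hr_bpm == pytest.approx(expected.mean_hr_bpm)
        assert reading.rmssd_ms == pytest.approx(expected.rmssd_ms)

    def test_truth_series_never_mutated(self, resting_rr):
        before = resting_rr.beat_times_s.copy()
        model = DeviceErrorModel("noisy", beat_jitter_sd_ms=20,
                                 missed_beat_prob=0.05, extra_beat_prob=0.05)
        simulate_device_reading(resting_rr, model, seed=1)
        np.testing.assert_array_equal(resting_rr.beat_times_s, before)

    def test_integer_rounding(self):
        rr = simulate_rr_series(RRTruthConfig(
            duration_s=310, mean_hr_bpm=60.4, rmssd_target_ms=None,
            lf_amp_ms=0, hf_amp_ms=0, vlf_drift_ms=0, jitter_sd_ms=0))
        model = DeviceErrorModel("round", hr_integer_rounding=True)
        reading = simulate_device_reading(rr, model, seed=0)
        assert reading.hr_bpm == 60.0

    def test_short_truth_rejected(self):
        rr = simulate_rr_series(RRTruthConfig(duration_s=60, seed=0))
        with pytest.raises(ValueError):
            simulate_device_reading(rr, DeviceErrorModel("x", epoch_s=300))

    def test_injected_bias_recovered_by_bland_altman(self):
        # additive HR bias of the magnitude seen in the worst camera-PPG
        # device should come straight back out of the BA bias estimate
        bias = 11.14
        model = DeviceErrorModel("biased", additive_hr_bias_bpm=bias)
        dev, ref = [], []
        for seed in range(120):
            rr = simulate_rr_series(RRTruthConfig(
                duration_s=310, mean_hr_bpm=65, rmssd_target_ms=45,
                seed=seed))
            reading = simulate_device_reading(rr, model, seed=seed)
            t = rr.beat_times_s
            truth = rr.__class__.from_beat_times(t[t < 300.0])
            dev.append(reading.hr_bpm)
            ref.append(summarize(truth, epoch_s=300).mean_hr_bpm)
        ba = bland_altman(dev, ref)
        assert ba.bias == pytest.approx(bias, abs=0.05)

    def test_conservation_without_miss_or_extra(self, resting_rr):
        # truncation never adds beats; jitter alone preserves the count
        model = DeviceErrorModel("jitter-only", beat_jitter_sd_ms=5.0)
        rng = np.random.default_rng(2)
        corrupted = corrupt_beats(resting_rr, model, rng)
        t = resting_rr.beat_times_s
        n_epoch = int(np.sum(t < t[0] + 300.0))
        assert corrupted.n_beats == n_epoch
        assert corrupted.n_beats <= resting_rr.n_beats


class TestGenerateStudy:
    def test_default_design_shape(self):
        ds = generate_study(StudyDesign(master_seed=3))
        assert len(ds.rr_series) == 148
        assert ds.trials["subject_id"].nunique() == 5
        assert ds.trials["device_label"].nunique() == 7
        per_device = ds.trials.groupby("device_label")["trial_id"].nunique()
        assert per_device.sum() == 148

    def test_master_seed_determinism(self):
        a = generate_study(StudyDesign(master_seed=9))
        b = generate_study(StudyDesign(master_seed=9))
        assert a.trials.equals(b.trials)
        for tid in a.rr_series:
            np.testing.assert_array_equal(
                a.rr_series[tid].beat_times_s, b.rr_series[tid].beat_times_s
            )

    def test_min_hr_device_has_no_hr_rows(self):
        ds = generate_study(StudyDesign(master_seed=3))
        hr_devices = set(ds.trials.loc[ds.trials.metric == "HR",
                                       "device_label"])
        assert "OURA" not in hr_devices
        rmssd_devices = set(ds.trials.loc[ds.trials.metric == "rMSSD",
                                          "device_label"])
        assert "OURA" in rmssd_devices

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_subjects=10, n_trials_total=5)
        with pytest.raises(ValueError):
            StudyDesign(device_panel=[])
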
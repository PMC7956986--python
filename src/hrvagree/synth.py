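"""Synthetic cardiac data with the structure of a wearable-validation study.

Generates ground-truth RR series with controllable rMSSD, renders them as
QRS-like ECG traces at a chosen sampling rate, corrupts them with
device-specific error models, and assembles whole studies (subjects x trials
x device panel) reproducible from a single master seed.

The RR model is direct modulation of the interval sequence:

    RR(t_i) = base + LF sinusoid + HF sinusoid + VLF half-cycle drift
              + white jitter

chosen because its rMSSD has a closed form (each sinusoid of amplitude A and
frequency f contributes ``2 A^2 sin^2(pi f tau)`` to the mean squared
successive difference at mean beat interval tau, white jitter of SD s
contributes ``2 s^2``), which lets the generator calibrate the HF amplitude
and jitter against a requested rMSSD target.  It is a statistical stand-in
for resting sinus rhythm, not an integral-pulse-frequency cardiac model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hrv
from .series import ECGRecord, RRSeries

__all__ = [
    "RRTruthConfig",
    "DeviceErrorModel",
    "StudyDesign",
    "DeviceReading",
    "CalibrationError",
    "corrupt_beats",
    "simulate_rr_series",
    "render_ecg",
    "simulate_device_reading",
    "generate_study",
    "default_device_panel",
]


class CalibrationError(ValueError):
    """Requested rMSSD target unreachable with the configured amplitudes."""


@dataclass(frozen=True)
class RRTruthConfig:
    """Ground-truth RR generator settings for one trial.

    All amplitudes in ms.  ``rmssd_target_ms`` (when not None) triggers
    internal calibration of the HF amplitude and white jitter; set it to
    None to use the amplitudes verbatim.
    """

    duration_s: float = 300.0
    mean_hr_bpm: float = 65.0
    rmssd_target_ms: float | None = 45.0
    lf_amp_ms: float = 10.0
    hf_amp_ms: float = 20.0
    lf_freq_hz: float = 0.10
    hf_freq_hz: float = 0.25
    vlf_drift_ms: float = 15.0
    jitter_sd_ms: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 30.0 <= self.mean_hr_bpm <= 220.0:
            raise ValueError("mean_hr_bpm must lie in [30, 220]")
        for name in ("lf_amp_ms", "hf_amp_ms", "vlf_drift_ms", "jitter_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rmssd_target_ms is not None and self.rmssd_target_ms < 0:
            raise ValueError("rmssd_target_ms must be >= 0 or None")


@dataclass(frozen=True)
class DeviceErrorModel:
    """Error characteristics of one commercial device/app pairing.

    Beat-level corruption (timing jitter, missed/extra beats) is applied to
    the detected beat sequence before summary metrics are recomputed;
    additive and proportional errors then act on the summary values
    themselves, mirroring how consumer apps post-process.
    """

    label: str
    additive_hr_bias_bpm: float = 0.0
    additive_rmssd_bias_ms: float = 0.0
    proportional_noise_cv: float = 0.0
    beat_jitter_sd_ms: float = 0.0
    missed_beat_prob: float = 0.0
    extra_beat_prob: float = 0.0
    epoch_s: float = 300.0
    reports_min_hr_not_mean: bool = False
    hr_integer_rounding: bool = False

    def __post_init__(self) -> None:
        for name in ("missed_beat_prob", "extra_beat_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.epoch_s not in (180.0, 300.0, 180, 300):
            raise ValueError("epoch_s must be 180 or 300 seconds")
        if self.proportional_noise_cv < 0:
            raise ValueError("proportional_noise_cv must be >= 0")


@dataclass(frozen=True)
class DeviceReading:
    """Summary values a commercial device reports for one trial."""

    device_label: str
    hr_bpm: float
    rmssd_ms: float
    epoch_s: float
    hr_is_min: bool = False


def default_device_panel() -> list[DeviceErrorModel]:
    """Seven-device panel emulating the study's COTS line-up.

    Error magnitudes echo the published per-device performance: a
    chest-strap that rounds HR to the integer and otherwise reports nearly
    perfectly but degrades on 3-min rMSSD; ECG-app pairings with sub-bpm
    biases; finger-PPG pairings with moderate proportional noise; a ring
    that reports minimum rather than mean HR; and a camera-PPG app with
    large bias and heavy noise.
    """
    return [
        DeviceErrorModel("FSTBT", epoch_s=180, hr_integer_rounding=True,
                         additive_rmssd_bias_ms=-12.0,
                         beat_jitter_sd_ms=10.0),
        DeviceErrorModel("ELT/ECG", epoch_s=300,
                         additive_hr_bias_bpm=-0.3,
                         proportional_noise_cv=0.05,
                         beat_jitter_sd_ms=3.0),
        DeviceErrorModel("HRV4TR/ECG", epoch_s=300,
                         additive_hr_bias_bpm=-1.0,
                         additive_rmssd_bias_ms=-0.7,
                         proportional_noise_cv=0.03),
        DeviceErrorModel("ELT/PPG", epoch_s=300,
                         additive_hr_bias_bpm=0.3,
                         additive_rmssd_bias_ms=3.6,
                         proportional_noise_cv=0.07,
                         beat_jitter_sd_ms=6.0),
        DeviceErrorModel("HRV4TR/PPG", epoch_s=300,
                         additive_rmssd_bias_ms=3.0,
                         proportional_noise_cv=0.08,
                         beat_jitter_sd_ms=6.0),
        DeviceErrorModel("OURA", epoch_s=300, reports_min_hr_not_mean=True,
                         additive_rmssd_bias_ms=-2.3,
                         proportional_noise_cv=0.06),
        DeviceErrorModel("CAMHRV", epoch_s=180,
                         additive_hr_bias_bpm=11.1,
                         additive_rmssd_bias_ms=78.0,
                         proportional_noise_cv=0.40,
                         beat_jitter_sd_ms=15.0,
                         missed_beat_prob=0.005,
                         extra_beat_prob=0.005),
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Whole-study layout: subjects, trial count, device panel, populations.

    Between-subject population parameters describe resting young adults:
    mean HR ~ 65 +/- 7 bpm, rMSSD ~ 50 +/- 15 ms between subjects, with
    trial-to-trial within-subject wobble on top.
    """

    n_subjects: int = 5
    n_trials_total: int = 148
    device_panel: list[DeviceErrorModel] = field(
        default_factory=default_device_panel
    )
    hr_population_mean_bpm: float = 65.0
    hr_between_sd_bpm: float = 7.0
    hr_within_sd_bpm: float = 3.0
    rmssd_population_mean_ms: float = 60.0
    rmssd_between_sd_ms: float = 15.0
    rmssd_within_sd_ms: float = 6.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_total < self.n_subjects:
            raise ValueError("need at least one trial per subject")
        if not self.device_panel:
            raise ValueError("device panel must be non-empty")


# ---------------------------------------------------------------------------
# RR ground truth

def _closed_form_rmssd(cfg: RRTruthConfig, hf_amp: float,
                       jitter_sd: float) -> float:
    tau = 60.0 / cfg.mean_hr_bpm  # mean beat interval, s
    vlf_freq = 0.5 / cfg.duration_s  # drift = half sine cycle over the record
    msd = 2.0 * jitter_sd**2
    for amp, freq in ((cfg.lf_amp_ms, cfg.lf_freq_hz),
                      (hf_amp, cfg.hf_freq_hz),
                      (cfg.vlf_drift_ms, vlf_freq)):
        msd += 2.0 * amp**2 * np.sin(np.pi * freq * tau) ** 2
    return float(np.sqrt(msd))


def _calibrate(cfg: RRTruthConfig) -> RRTruthConfig:
    """Scale hf_amp and jitter_sd by bisection so the closed-form rMSSD of
    the modulation model hits the target."""
    target = cfg.rmssd_target_ms
    assert target is not None
    floor = _closed_form_rmssd(cfg, 0.0, 0.0)  # LF + VLF contribution alone
    if target < floor - 1e-9:
        raise CalibrationError(
            f"rMSSD target {target:.1f} ms below the {floor:.1f} ms floor "
            "set by the LF/VLF amplitudes"
        )
    if cfg.hf_amp_ms == 0 and cfg.jitter_sd_ms == 0:
        if target > floor + 1e-9:
            raise CalibrationError(
                "target exceeds floor but hf_amp_ms and jitter_sd_ms are 0"
            )
        return cfg
    lo, hi = 0.0, 1.0
    while _closed_form_rmssd(cfg, hi * cfg.hf_amp_ms,
                             hi * cfg.jitter_sd_ms) < target:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError("bisection bracket exploded")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _closed_form_rmssd(cfg, mid * cfg.hf_amp_ms,
                              mid * cfg.jitter_sd_ms) < target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return replace(cfg, hf_amp_ms=c * cfg.hf_amp_ms,
                   jitter_sd_ms=c * cfg.jitter_sd_ms, rmssd_target_ms=None)


def simulate_rr_series(config: RRTruthConfig) -> RRSeries:
    """Ground-truth RR series for one trial; deterministic in the seed.

    Beat times start at 0 and run to ~``duration_s``.  When
    ``rmssd_target_ms`` is set, the HF amplitude and jitter SD are first
    rescaled so the model's closed-form rMSSD matches it; realized rMSSD then
    lands within ~10% of the target (Monte-Carlo mean over seeds), and the
    realized mean HR within ~2% of ``mean_hr_bpm``.
    """
    cfg = config
    if cfg.rmssd_target_ms is not None:
        cfg = _calibrate(cfg)
    rng = np.random.default_rng(cfg.seed)
    base_ms = 60000.0 / cfg.mean_hr_bpm
    lf_phase, hf_phase = rng.uniform(0, 2 * np.pi, size=2)
    vlf_sign = rng.choice([-1.0, 1.0])
    n_max = int(np.ceil(cfg.duration_s / (base_ms / 1000.0) * 2)) + 4
    jitter = rng.normal(0.0, cfg.jitter_sd_ms, size=n_max) \
        if cfg.jitter_sd_ms > 0 else np.zeros(n_max)

    times = [0.0]
    t = 0.0
    i = 0
    while t < cfg.duration_s and i < n_max:
        rr = (
            base_ms
            + cfg.lf_amp_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t + lf_phase)
            + cfg.hf_amp_ms * np.sin(2 * np.pi * cfg.hf_freq_hz * t + hf_phase)
            + vlf_sign * cfg.vlf_drift_ms
            * np.sin(np.pi * t / cfg.duration_s)
            + jitter[i]
        )
        rr = max(rr, 250.0)  # physiologic hard floor on the truth
        t += rr / 1000.0
        times.append(t)
        i += 1
    if len(times) < 2:
        raise ValueError("configuration produced fewer than 2 beats")
    return RRSeries.from_beat_times(times)


# ---------------------------------------------------------------------------
# ECG rendering

QRS_WIDTH_S = 0.080  # total template support
QRS_AMPLITUDE_MV = 1.0


def _ricker(t: np.ndarray, a: float) -> np.ndarray:
    """Mexican-hat wavelet, peak 1 at t = 0, characteristic scale ``a``."""
    x = t / a
    return (1.0 - x * x) * np.exp(-0.5 * x * x)


def render_ecg(rr: RRSeries, fs_hz: float = 512.0,
               snr_db: float = np.inf,
               seed: int = 0) -> tuple[ECGRecord, np.ndarray]:
    """Render an RR series as a synthetic single-lead ECG.

    One Ricker (Mexican-hat) template of 80 ms support and 1 mV peak is
    centred at each beat time — any sharp biphasic waveform suffices for
    peak-detection work — plus white Gaussian noise at ``snr_db`` relative
    to the clean signal power (infinite SNR means no noise).

    Returns the record and the ground-truth beat sample indices.
    """
    if rr.n_beats < 1:
        raise ValueError("empty RR series")
    if fs_hz < 128:
        raise ValueError("fs_hz too low to represent the QRS template")
    span = rr.beat_times_s[-1] - rr.beat_times_s[0]
    n = int(np.ceil((span + 2 * QRS_WIDTH_S) * fs_hz)) + 1
    sig = np.zeros(n)
    t0 = rr.beat_times_s[0] - QRS_WIDTH_S
    a = QRS_WIDTH_S / 6.0  # template decays well inside the 80 ms support
    half = int(round(QRS_WIDTH_S / 2 * fs_hz))
    tpl_t = np.arange(-half, half + 1) / fs_hz
    tpl = QRS_AMPLITUDE_MV * _ricker(tpl_t, a)
    beat_idx = np.round((rr.beat_times_s - t0) * fs_hz).astype(int)
    for b in beat_idx:
        lo = b - half
        hi = b + half + 1
        s0 = max(0, -lo)
        s1 = tpl.size - max(0, hi - n)
        sig[max(0, lo):min(n, hi)] += tpl[s0:s1]
    if np.isfinite(snr_db):
        power = np.mean(sig**2)
        noise_sd = np.sqrt(power / 10 ** (snr_db / 10.0))
        sig = sig + np.random.default_rng(seed).normal(0, noise_sd, n)
    return ECGRecord(fs_hz=fs_hz, samples=sig, start_time_s=t0), beat_idx


# ---------------------------------------------------------------------------
# device simulation

def corrupt_beats(rr_truth: RRSeries, model: DeviceErrorModel,
                  rng: np.random.Generator) -> RRSeries:
    """Beat-level corruption only: truncate to the device epoch, then apply
    missed beats, extra beats and timing jitter (in that fixed order).

    With zero miss/extra probabilities the beat count is preserved exactly;
    truncation never adds beats.  The truth series is never mutated.
    """
    start = rr_truth.beat_times_s[0]
    if rr_truth.beat_times_s[-1] - start < model.epoch_s:
        raise ValueError("truth series shorter than the device epoch")
    t = rr_truth.beat_times_s.copy()
    t = t[t < start + model.epoch_s]

    if model.missed_beat_prob > 0 and t.size > 2:
        interior = rng.random(t.size - 2) >= model.missed_beat_prob
        t = np.concatenate(([t[0]], t[1:-1][interior], [t[-1]]))
    if model.extra_beat_prob > 0 and t.size > 1:
        extras = []
        gaps = np.diff(t)
        hit = rng.random(gaps.size) < model.extra_beat_prob
        for i in np.flatnonzero(hit):
            extras.append(t[i] + rng.uniform(0.25, 0.75) * gaps[i])
        if extras:
            t = np.sort(np.concatenate([t, extras]))
    if model.beat_jitter_sd_ms > 0:
        t = t + rng.normal(0, model.beat_jitter_sd_ms / 1000.0, t.size)
        t = np.sort(t)
        # collapse collisions the jitter may create
        keep = np.concatenate(([True], np.diff(t) > 1e-4))
        t = t[keep]
    return RRSeries.from_beat_times(t)


def simulate_device_reading(rr_truth: RRSeries, model: DeviceErrorModel,
                            seed: int = 0) -> DeviceReading:
    """Corrupt a truth series the way one commercial device would.

    Order is fixed: beat-level corruption via :func:`corrupt_beats`
    (truncation, missed/extra beats, timing jitter), then the summary
    metrics are recomputed and the summary-level errors applied —
    proportional noise, additive bias, optional integer rounding.
    """
    rng = np.random.default_rng(seed)
    corrupted = corrupt_beats(rr_truth, model, rng)
    summ = hrv.summarize(corrupted, epoch_s=model.epoch_s)
    hr = summ.min_hr_bpm if model.reports_min_hr_not_mean else summ.mean_hr_bpm
    rmssd_val = summ.rmssd_ms

    if model.proportional_noise_cv > 0:
        hr *= 1.0 + rng.normal(0, model.proportional_noise_cv)
        rmssd_val *= 1.0 + rng.normal(0, model.proportional_noise_cv)
    hr += model.additive_hr_bias_bpm
    rmssd_val += model.additive_rmssd_bias_ms
    rmssd_val = max(rmssd_val, 0.0)
    if model.hr_integer_rounding:
        hr = float(np.round(hr))
    return DeviceReading(
        device_label=model.label, hr_bpm=float(hr),
        rmssd_ms=float(rmssd_val), epoch_s=model.epoch_s,
        hr_is_min=model.reports_min_hr_not_mean,
    )


# ---------------------------------------------------------------------------
# whole-study generation

def _allocate_trials(n_total: int, n_devices: int) -> list[int]:
    """Near-equal split; the remainder goes to the first devices."""
    base, extra = divmod(n_total, n_devices)
    return [base + (1 if i < extra else 0) for i in range(n_devices)]


def generate_study(design: StudyDesign = StudyDesign()):
    """Simulate a complete validation study from one master seed.

    Returns a :class:`hrvagree.pipeline.StudyDataset`: a trial table (one
    row per trial and metric, with the device's reported value) plus the
    per-trial ground-truth RR series.  Subjects' resting HR and rMSSD are
    drawn from the design's between-subject distributions; each trial adds
    within-subject variation.
    """
    from .pipeline import StudyDataset  # local import avoids a cycle

    import pandas as pd

    rng = np.random.default_rng(design.master_seed)
    subj_hr = rng.normal(design.hr_population_mean_bpm,
                         design.hr_between_sd_bpm, design.n_subjects)
    subj_rmssd = rng.normal(design.rmssd_population_mean_ms,
                            design.rmssd_between_sd_ms, design.n_subjects)
    subj_hr = np.clip(subj_hr, 45.0, 100.0)
    subj_rmssd = np.clip(subj_rmssd, 15.0, 120.0)

    counts = _allocate_trials(design.n_trials_total, len(design.device_panel))
    rows = []
    rr_store: dict[int, RRSeries] = {}
    trial_id = 0
    for dev, n_dev in zip(design.device_panel, counts):
        for k in range(n_dev):
            subject = trial_id % design.n_subjects
            hr = float(np.clip(
                subj_hr[subject] + rng.normal(0, design.hr_within_sd_bpm),
                40.0, 150.0))
            rm = float(np.clip(
                subj_rmssd[subject]
                + rng.normal(0, design.rmssd_within_sd_ms), 8.0, 150.0))
            seed_t = int(rng.integers(0, 2**31 - 1))
            cfg = RRTruthConfig(
                duration_s=dev.epoch_s + 10.0, mean_hr_bpm=hr,
                rmssd_target_ms=rm, seed=seed_t,
            )
            truth = simulate_rr_series(cfg)
            reading = simulate_device_reading(
                truth, dev, seed=int(rng.integers(0, 2**31 - 1)))
            rr_store[trial_id] = truth
            common = dict(
                trial_id=trial_id, subject_id=f"S{subject + 1}",
                device_label=dev.label, epoch_start_s=0.0,
                epoch_s=float(dev.epoch_s),
            )
            if not dev.reports_min_hr_not_mean:
                rows.append({**common, "metric": "HR",
                             "device_value": reading.hr_bpm, "units": "bpm"})
            rows.append({**common, "metric": "rMSSD",
                         "device_value": reading.rmssd_ms, "units": "ms"})
            trial_id += 1
    trials = pd.DataFrame(rows)
    return StudyDataset(trials=trials, rr_series=rr_store,
                        meta={"master_seed": design.master_seed,
                              "n_subjects": design.n_subjects,
                              "n_trials_total": design.n_trials_total})
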
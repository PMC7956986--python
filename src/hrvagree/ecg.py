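"""Reference-ECG processing: R-peak detection and RR-interval extraction.

Turns a sampled ECG voltage trace into a timestamp-aligned RR series — the
role the commercial HRV analysis software played in the validation study it
emulates.  The detector follows the classic Pan-Tompkins stages: 5-15 Hz
band-pass, differentiation, squaring, 150 ms moving-window integration,
adaptive dual thresholds with a 200 ms refractory period, and a search-back
pass for beats missed at the running threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.signal

from .series import RR_GATE_MS, ECGRecord, RRSeries

__all__ = ["detect_r_peaks", "extract_ibis", "segment_by_timestamps"]

REFRACTORY_S = 0.200
BANDPASS_HZ = (5.0, 15.0)
INTEGRATION_WINDOW_S = 0.150


def _preprocess(ecg: ECGRecord) -> tuple[np.ndarray, np.ndarray]:
    """Band-passed signal and its moving-window-integrated squared slope."""
    fs = ecg.fs_hz
    nyq = fs / 2.0
    lo, hi = BANDPASS_HZ
    sos = scipy.signal.butter(2, [lo / nyq, min(hi / nyq, 0.99)],
                              btype="bandpass", output="sos")
    # zero-phase filtering keeps the filtered peak aligned with the R wave
    band = scipy.signal.sosfiltfilt(sos, ecg.samples)
    deriv = np.gradient(band) * fs
    squared = deriv * deriv
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    integ = scipy.signal.convolve(
        squared, np.ones(win) / win, mode="same"
    )
    return band, integ


def detect_r_peaks(ecg: ECGRecord) -> np.ndarray:
    """Detect R-peak times (seconds, on the record's clock).

    Returns a strictly increasing array of beat times.  A signal with no
    QRS-like activity yields an empty array with a warning rather than an
    error.  Output is invariant to a DC offset (the band-pass removes it).
    """
    if ecg.duration_s < 2.0:
        raise ValueError("record too short for detection (< 2 s)")
    if not np.all(np.isfinite(ecg.samples)):
        raise ValueError("non-finite samples in ECG record")
    fs = ecg.fs_hz
    band, integ = _preprocess(ecg)
    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = scipy.signal.find_peaks(integ, distance=refractory)
    if cand.size == 0 or np.max(integ) <= 0:
        warnings.warn("no candidate peaks found in record", stacklevel=2)
        return np.array([])

    # adaptive dual thresholds (running signal/noise peak estimates)
    learn = integ[: int(2 * fs)]
    spki = 0.25 * float(np.max(learn))
    npki = 0.5 * float(np.mean(learn))
    accepted: list[int] = []
    rr_hist: list[float] = []
    pending: list[int] = []  # sub-threshold candidates for search-back

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in cand:
        peak = integ[p]
        if peak > threshold():
            accepted.append(int(p))
            spki = 0.125 * peak + 0.875 * spki
            if len(accepted) >= 2:
                rr_hist.append(accepted[-1] - accepted[-2])
                rr_hist[:] = rr_hist[-8:]
            pending.clear()
        else:
            npki = 0.125 * peak + 0.875 * npki
            pending.append(int(p))
            # search-back: missed-beat window at 1.66x the running RR mean
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if p - accepted[-1] > 1.66 * rr_avg:
                    sub = [q for q in pending if q - accepted[-1] > refractory]
                    if sub:
                        best = max(sub, key=lambda q: integ[q])
                        if integ[best] > 0.5 * threshold():
                            accepted.append(best)
                            accepted.sort()
                            spki = 0.25 * integ[best] + 0.75 * spki
                            rr_hist.append(accepted[-1] - accepted[-2])
                            rr_hist[:] = rr_hist[-8:]
                            pending.clear()

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold", stacklevel=2)
        return np.array([])

    # refine each fiducial to the band-passed local maximum (R apex)
    half = int(round(0.100 * fs))
    refined = []
    for p in accepted:
        lo_i = max(0, p - half)
        hi_i = min(band.size, p + half + 1)
        refined.append(lo_i + int(np.argmax(band[lo_i:hi_i])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    return ecg.start_time_s + np.asarray(keep, dtype=float) / fs


def extract_ibis(beat_times_s, gate_ms: tuple[float, float] = RR_GATE_MS
                 ) -> tuple[RRSeries, np.ndarray]:
    """Inter-beat intervals from R-peak times.

    Returns the RR series plus a boolean mask marking intervals inside the
    physiologic gate (default 300-2000 ms).  Out-of-gate intervals are
    flagged for per-trial exclusion, never silently dropped or interpolated.
    """
    t = np.asarray(beat_times_s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 beat times")
    if not np.all(np.diff(t) > 0):
        raise ValueError("beat times must be strictly increasing")
    rr = RRSeries.from_beat_times(t)
    return rr, rr.gate_mask(gate_ms)


def segment_by_timestamps(rr: RRSeries, start_s: float,
                          duration_s: float) -> RRSeries:
    """Beats inside the half-open epoch window ``[start, start+duration)``.

    Intervals are recomputed from the retained beats only; the half-open
    convention prevents a boundary beat being counted by two adjacent
    epochs.  Idempotent for a fixed window.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = rr.beat_times_s
    mask = (t >= start_s) & (t < start_s + duration_s)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 beats")
    return RRSeries.from_beat_times(t[mask])
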
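"""Time-domain HRV summary metrics: detrended rMSSD, mean HR, minimum HR.

The reference pipeline removes very-low-frequency trend from the RR sequence
with the smoothing-priors regularised least-squares estimator before computing
rMSSD, because slow trends inflate a metric that is meant to index short-term
(parasympathetic) variability.  The smoothing parameter lambda controls the
high-pass cut-off; lambda = 400 interpreted at a 4 Hz effective sampling rate
gives the conventional ~0.039 Hz half-power cut-off, below the low-frequency
band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse

from .series import RRSeries

__all__ = [
    "DetrendConfig",
    "HrvSummary",
    "smoothing_priors_detrend",
    "detrend_cutoff_frequency",
    "rmssd",
    "mean_hr",
    "min_hr",
]


@dataclass(frozen=True)
class DetrendConfig:
    """Smoothing-priors detrending parameters.

    lambda_ : regularisation weight (unitless; study convention 400).
    effective_fs_hz : rate at which the cut-off frequency of the implied
        high-pass filter is interpreted, in Hz (default 4, the conventional
        RR-resampling rate in the smoothing-priors literature).
    """

    lambda_: float = 400.0
    effective_fs_hz: float = 4.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.effective_fs_hz <= 0:
            raise ValueError("effective_fs_hz must be > 0")


@dataclass(frozen=True)
class HrvSummary:
    """Per-epoch physiological summary, the quantities devices report."""

    mean_hr_bpm: float
    min_hr_bpm: float
    rmssd_ms: float
    rmssd_raw_ms: float
    n_beats: int
    epoch_s: float


def _second_difference(n: int) -> scipy.sparse.csr_matrix:
    """(n-2) x n second-difference operator D2."""
    return scipy.sparse.diags(
        [1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n)
    ).tocsr()


def smoothing_priors_detrend(z, cfg: DetrendConfig = DetrendConfig()) -> np.ndarray:
    """Remove the smoothing-priors trend from an interval sequence.

    The trend is the regularised least-squares fit
    ``trend = (I + lambda^2 D2' D2)^{-1} z`` where D2 is the second-difference
    operator; the returned detrended sequence is ``z - trend``.  With
    lambda = 0 the trend equals the signal and the output is identically zero;
    as lambda grows the trend tends to the least-squares line (the null space
    of D2), so the output tends to the linear-regression residuals.

    Parameters
    ----------
    z : array-like or RRSeries
        Interval sequence in ms, indexed by beat number.
    cfg : DetrendConfig

    Returns
    -------
    ndarray
        Zero-trend fluctuation component, same length as ``z``.
    """
    if isinstance(z, RRSeries):
        z = z.rr_ms
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("need at least 3 intervals to detrend")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in interval sequence")
    if cfg.lambda_ == 0:
        return np.zeros_like(z)
    n = z.size
    d2 = _second_difference(n)
    a = scipy.sparse.identity(n, format="csr") + cfg.lambda_**2 * (d2.T @ d2)
    # symmetric pentadiagonal normal equations: banded Cholesky is O(n)
    ab = np.zeros((3, n))
    ab[2] = a.diagonal(0)
    ab[1, 1:] = a.diagonal(1)
    ab[0, 2:] = a.diagonal(2)
    try:
        trend = scipy.linalg.solveh_banded(ab, z, lower=False)
    except np.linalg.LinAlgError:
        # extreme lambda: the normal equations condition on lambda^2 and can
        # lose positive definiteness in double precision; solve the
        # equivalent stacked least squares [I; lambda*D2] trend ~ [z; 0],
        # which conditions on lambda and recovers the OLS-residual limit
        stacked = np.vstack([np.eye(n), cfg.lambda_ * d2.toarray()])
        rhs = np.concatenate([z, np.zeros(n - 2)])
        trend, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
    return z - trend


def detrend_cutoff_frequency(cfg: DetrendConfig) -> float:
    """Half-power cut-off (Hz) of the detrending high-pass response.

    The detrender acts on the sequence as a high-pass with frequency response
    ``G(w) = lambda^2 a(w) / (1 + lambda^2 a(w))`` where
    ``a(w) = 16 sin^4(w/2)`` (the squared gain of the second difference).
    The half-power point solves ``G(w) = 1/sqrt(2)`` and is mapped to Hz via
    ``effective_fs_hz``.  Monotonically decreasing in lambda.
    """
    if cfg.lambda_ <= 0:
        raise ValueError("cut-off undefined for lambda = 0 (no pass-band)")
    # G = 1/sqrt(2)  =>  lambda^2 a = 1/(sqrt(2)-1)  =>  a known, invert sin^4
    a = 1.0 / ((np.sqrt(2.0) - 1.0) * cfg.lambda_**2)
    arg = (a / 16.0) ** 0.25
    if arg > 1.0:
        raise ValueError("lambda too small: half-power point above Nyquist")
    w = 2.0 * np.arcsin(arg)
    return float(w * cfg.effective_fs_hz / (2.0 * np.pi))


def rmssd(rr, detrend: DetrendConfig | None = None) -> float:
    """Root mean square of successive RR-interval differences, in ms.

    Computes ``sqrt(mean((rr[i+1] - rr[i])^2))``.  When a detrend config is
    given, successive differences are taken on the smoothing-priors detrended
    sequence instead of the raw one.
    """
    if isinstance(rr, RRSeries):
        rr = rr.rr_ms
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("rMSSD needs at least 2 intervals")
    if not np.all(np.isfinite(rr)):
        raise ValueError("non-finite RR intervals")
    if detrend is not None:
        rr = smoothing_priors_detrend(rr, detrend)
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def mean_hr(rr) -> float:
    """Mean heart rate over the epoch, bpm.

    Convention: ``60000 / mean(rr_ms)`` — beats per elapsed time, consistent
    with an "average HR" summary of an epoch (not the mean of instantaneous
    rates, which weights short intervals more).
    """
    if isinstance(rr, RRSeries):
        rr = rr.rr_ms
    rr = np.asarray(rr, dtype=float)
    if rr.size < 1:
        raise ValueError("mean HR needs at least 1 interval")
    return float(60000.0 / np.mean(rr))


def min_hr(rr: RRSeries, window_s: float = 10.0) -> float:
    """Minimum windowed heart rate over the epoch, bpm.

    Slides a window of ``window_s`` seconds across the beat times and takes
    the minimum of the windowed mean HR (``60000 / mean(rr in window)``).
    Ring-style devices report this rather than the epoch mean; their actual
    window length is unpublished, so it is a parameter here (default 10 s).
    """
    if not isinstance(rr, RRSeries):
        rr = RRSeries.from_rr_ms(np.asarray(rr, dtype=float))
    if rr.duration_s < window_s:
        raise ValueError("series shorter than the min-HR window")
    t = rr.beat_times_s
    best = np.inf
    j = 0
    for i in range(rr.n_beats):
        end = t[i] + window_s
        j = max(j, i + 1)
        while j < rr.n_beats and t[j] < end:
            j += 1
        # intervals i..j-2 lie fully inside [t[i], t[i]+window_s)
        if j - 1 > i:
            hr = 60000.0 / np.mean(rr.rr_ms[i : j - 1])
            best = min(best, hr)
        if j == rr.n_beats:
            break
    if not np.isfinite(best):
        raise ValueError("no window contained a full interval")
    return float(best)


def summarize(rr: RRSeries, epoch_s: float,
              detrend: DetrendConfig | None = DetrendConfig(),
              min_hr_window_s: float = 10.0) -> HrvSummary:
    """Compute the full per-epoch summary a validation trial compares."""
    raw = rmssd(rr)
    det = rmssd(rr, detrend) if detrend is not None and rr.rr_ms.size >= 3 else raw
    return HrvSummary(
        mean_hr_bpm=mean_hr(rr),
        min_hr_bpm=min_hr(rr, min_hr_window_s),
        rmssd_ms=det,
        rmssd_raw_ms=raw,
        n_beats=rr.n_beats,
        epoch_s=epoch_s,
    )
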
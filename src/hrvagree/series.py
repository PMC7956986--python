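"""Core carriers of cardiac timing data.

``RRSeries`` holds beat times and the inter-beat (RR) intervals derived from
them; every HRV computation in this package consumes it.  ``ECGRecord`` holds
a uniformly sampled single-channel voltage trace, the reference signal from
which beats are detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physiologic plausibility gate for RR intervals, in ms.  Intervals outside
#: this range are flagged (never silently dropped) so callers can exclude the
#: trial; no ectopic-beat interpolation is attempted.
RR_GATE_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class RRSeries:
    """Ordered heartbeat times with their successive differences.

    Parameters
    ----------
    beat_times_s : ndarray
        Strictly increasing beat (R-peak) times in seconds.
    rr_ms : ndarray
        Successive differences in milliseconds, ``len == len(beat_times_s)-1``.
        Always derived from the beat times; use :meth:`from_beat_times`.
    """

    beat_times_s: np.ndarray
    rr_ms: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("beat_times_s must be one-dimensional")
        if not np.all(np.isfinite(t)):
            raise ValueError("beat times must be finite")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times_s", t)
        object.__setattr__(self, "rr_ms", np.diff(t) * 1000.0)

    @classmethod
    def from_beat_times(cls, beat_times_s) -> "RRSeries":
        return cls(np.asarray(beat_times_s, dtype=float))

    @classmethod
    def from_rr_ms(cls, rr_ms, start_time_s: float = 0.0) -> "RRSeries":
        """Build a series whose first beat is at ``start_time_s``."""
        rr = np.asarray(rr_ms, dtype=float)
        if rr.size < 1:
            raise ValueError("need at least one interval")
        t = start_time_s + np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
        return cls(t)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times_s.size)

    @property
    def duration_s(self) -> float:
        if self.n_beats < 2:
            return 0.0
        return float(self.beat_times_s[-1] - self.beat_times_s[0])

    def gate_mask(self, gate_ms: tuple[float, float] = RR_GATE_MS) -> np.ndarray:
        """Boolean mask of intervals inside the physiologic gate."""
        lo, hi = gate_ms
        return (self.rr_ms >= lo) & (self.rr_ms <= hi)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table ``(beat_time_s, rr_ms)``; rr is NaN for beat 0."""
        rr = np.concatenate(([np.nan], self.rr_ms))
        return pd.DataFrame({"beat_time_s": self.beat_times_s, "rr_ms": rr})

    def to_csv(self, path) -> None:
        # %.17g guarantees a bit-exact float round trip through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "RRSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_beat_times(df["beat_time_s"].to_numpy())


@dataclass(frozen=True)
class ECGRecord:
    """Uniformly sampled single-channel ECG voltage trace.

    Attributes
    ----------
    fs_hz : float
        Sampling rate; the reference recordings this package emulates were
        sampled at 512 Hz.
    samples : ndarray
        Voltage in mV.
    start_time_s : float
        Recording-clock offset of sample 0.
    """

    fs_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs_hz

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "mv": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def read_csv(cls, path) -> "ECGRecord":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("ECG CSV must contain at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(fs_hz=fs, samples=df["mv"].to_numpy(), start_time_s=float(t[0]))
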
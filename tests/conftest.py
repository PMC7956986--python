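import numpy as np
import pytest

from hrvagree import RRSeries, RRTruthConfig, simulate_rr_series


@pytest.fixture
def constant_rr() -> RRSeries:
    """30 beats at exactly 1000 ms."""
    return RRSeries.from_rr_ms([1000.0] * 29)


@pytest.fixture
def resting_rr() -> RRSeries:
    """A 5-min resting-state truth series (65 bpm, rMSSD target 45 ms)."""
    return simulate_rr_series(
        RRTruthConfig(duration_s=300, mean_hr_bpm=65,
                      rmssd_target_ms=45, seed=7)
    )


def match_beats(detected_s: np.ndarray, truth_s: np.ndarray,
                tol_s: float) -> tuple[float, float]:
    """(sensitivity, positive predictivity) of detected vs truth beats."""
    if detected_s.size == 0:
        return 0.0, 0.0
    d_truth = np.min(np.abs(truth_s[:, None] - detected_s[None, :]), axis=1)
    d_det = np.min(np.abs(detected_s[:, None] - truth_s[None, :]), axis=1)
    sens = float(np.mean(d_truth <= tol_s))
    ppv = float(np.mean(d_det <= tol_s))
    return sens, ppv
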
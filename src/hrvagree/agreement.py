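"""Method-agreement statistics for device-vs-reference paired measurements.

Implements the validation-study statistical chain: absolute percent error
(APE) against the reference, removal of extreme outliers by the Tukey outer
fence, APE summary statistics (MAPE, min, median, max, IQR), Lin's
concordance correlation coefficient, Bland-Altman limits of agreement with
their confidence intervals, and a Bonferroni-corrected paired t-test of zero
bias.

The chain is exposed both as plain functions and as a model/results pair:
``DeviceAgreement(device, reference).fit()`` returns an
:class:`AgreementResults` carrying every estimate with its uncertainty and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "absolute_percent_error",
    "tukey_extreme_outliers",
    "ape_summary",
    "lin_ccc",
    "bland_altman",
    "paired_bias_test",
    "ApeSummary",
    "BlandAltmanResult",
    "ConcordanceResult",
    "DeviceAgreement",
    "AgreementResults",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class ApeSummary:
    """APE summary statistics after extreme-outlier removal (all percent)."""

    n: int
    mape_pct: float
    min_pct: float
    median_pct: float
    max_pct: float
    iqr_pct: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement, with 95% CIs.

    Differences are device minus reference, so a positive bias means the
    device overestimates.  LOA = bias +/- z*SD with sample SD (n-1 ddof);
    CI of the bias uses t * SD/sqrt(n), CI of each LOA the classic
    t * SD * sqrt(3/n) standard-error approximation.
    """

    n: int
    bias: float
    bias_ci: tuple[float, float]
    lower_loa: float
    lower_loa_ci: tuple[float, float]
    upper_loa: float
    upper_loa_ci: tuple[float, float]
    loa_range: float
    sd_diff: float
    adjusted_p: float | None = None


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    ccc: float


# ---------------------------------------------------------------------------
# operations

def absolute_percent_error(device_value, reference_value):
    """APE of a device reading relative to the reference, in percent.

    ``|device - reference| / reference * 100``; the reference (HR in bpm or
    rMSSD in ms) must be strictly positive.
    """
    dev = np.asarray(device_value, dtype=float)
    ref = np.asarray(reference_value, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference values must be strictly positive")
    out = np.abs(dev - ref) / ref * 100.0
    return float(out) if out.ndim == 0 else out


def _quartiles(x: np.ndarray, method: str = "linear") -> tuple[float, float]:
    q1, q3 = np.quantile(x, [0.25, 0.75], method=method)
    return float(q1), float(q3)


def tukey_extreme_outliers(values, k: float = 3.0,
                           quartile_method: str = "linear") -> np.ndarray:
    """Boolean mask of values *kept* by the Tukey outer-fence rule.

    A value is flagged extreme when it lies above ``Q3 + k*IQR`` or below
    ``Q1 - k*IQR`` (k = 3, the outer fence).  Quartiles use linear
    interpolation between order statistics by default (numpy/R type 7);
    the estimator is configurable because fence membership can flip near
    boundaries.  Applied once, per device/metric group.  With fewer than 4
    values quartiles are not meaningful: nothing is removed and a warning is
    issued.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn(
            "fewer than 4 values: Tukey fences not applied", stacklevel=2
        )
        return np.ones(x.size, dtype=bool)
    q1, q3 = _quartiles(x, quartile_method)
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def ape_summary(ape_values, quartile_method: str = "linear") -> ApeSummary:
    """Summary statistics of a group's kept APE values (percent)."""
    x = np.asarray(ape_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty APE group")
    q1, q3 = (np.nan, np.nan) if x.size < 2 else _quartiles(x, quartile_method)
    return ApeSummary(
        n=int(x.size),
        mape_pct=float(np.mean(x)),
        min_pct=float(np.min(x)),
        median_pct=float(np.median(x)),
        max_pct=float(np.max(x)),
        iqr_pct=float(q3 - q1) if x.size >= 2 else 0.0,
    )


def lin_ccc(device_values, reference_values) -> ConcordanceResult:
    """Lin's concordance correlation coefficient.

    ``CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)`` with population
    (1/n) moments — Lin's 1989 sample version.  Measures agreement with the
    identity line: 1 only when the pairs are identical, and
    ``|CCC| <= |Pearson r|`` always (the bias-correction factor is <= 1).
    """
    x = np.asarray(device_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    sx2 = np.var(x)
    sy2 = np.var(y)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("CCC undefined for constant inputs")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    return ConcordanceResult(n=int(x.size), ccc=float(ccc))


def bland_altman(device_values, reference_values, alpha: float = 0.05,
                 loa_z: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman limits-of-agreement analysis of paired measurements.

    See :class:`BlandAltmanResult` for the conventions (device - reference
    differences, 1.96 multiplier, 1986-recipe CIs).
    """
    d = np.asarray(device_values, dtype=float) - np.asarray(
        reference_values, dtype=float
    )
    n = d.size
    if n < 3:
        raise ValueError("Bland-Altman needs >= 3 pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t = float(scipy.stats.t.ppf(1 - alpha / 2, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    lower = bias - loa_z * sd
    upper = bias + loa_z * sd
    return BlandAltmanResult(
        n=int(n),
        bias=bias,
        bias_ci=(bias - t * se_bias, bias + t * se_bias),
        lower_loa=lower,
        lower_loa_ci=(lower - t * se_loa, lower + t * se_loa),
        upper_loa=upper,
        upper_loa_ci=(upper - t * se_loa, upper + t * se_loa),
        loa_range=upper - lower,
        sd_diff=sd,
    )


def paired_bias_test(differences, n_comparisons: int = 1) -> float:
    """Bonferroni-adjusted p of a two-sided one-sample t-test of zero bias.

    ``p_adj = min(1, n_comparisons * p)``; callers declare significance at
    p_adj < 0.05.  A zero-variance difference vector has no defined t
    statistic and raises.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("t-test needs >= 2 differences")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: t-test degenerate")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    t = scipy.stats.ttest_1samp(d, popmean=0.0)
    return float(min(1.0, n_comparisons * t.pvalue))


# ---------------------------------------------------------------------------
# model / results

class DeviceAgreement:
    """Agreement model for one device/metric group of paired measurements.

    Parameters
    ----------
    device_values, reference_values : array-like
        Paired measurements in the same units (bpm or ms); the reference
        must be strictly positive.
    label : str
        Device identifier, carried into the summary.
    metric : str
        Metric name ("HR" or "rMSSD"), carried into the summary.
    """

    def __init__(self, device_values, reference_values,
                 label: str = "", metric: str = ""):
        self.device = np.asarray(device_values, dtype=float)
        self.reference = np.asarray(reference_values, dtype=float)
        if self.device.shape != self.reference.shape or self.device.ndim != 1:
            raise ValueError("device and reference must be equal-length 1-D")
        if not np.all(np.isfinite(self.reference)):
            raise ValueError("reference values must be finite")
        self.label = label
        self.metric = metric

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       device_col: str = "device_value",
                       reference_col: str = "reference_value",
                       label: str = "", metric: str = "") -> "DeviceAgreement":
        return cls(df[device_col].to_numpy(), df[reference_col].to_numpy(),
                   label=label, metric=metric)

    def fit(self, fence_k: float = 3.0, quartile_method: str = "linear",
            bonferroni_m: int = 1, alpha: float = 0.05,
            loa_z: float = 1.96) -> "AgreementResults":
        """Run the full agreement chain in the study's order.

        APE first, then extreme-outlier removal on the APE values; every
        downstream statistic (summary, CCC, Bland-Altman, bias t-test) is
        computed on the kept pairs only.
        """
        ape = absolute_percent_error(self.device, self.reference)
        keep = tukey_extreme_outliers(ape, k=fence_k,
                                      quartile_method=quartile_method)
        dev, ref = self.device[keep], self.reference[keep]
        summ = ape_summary(ape[keep], quartile_method)
        ba = bland_altman(dev, ref, alpha=alpha, loa_z=loa_z)
        d = dev - ref
        if np.std(d, ddof=1) > 0:
            p_adj = paired_bias_test(d, n_comparisons=bonferroni_m)
        else:
            p_adj = None  # zero-variance bias (e.g. a perfect device)
        ba = BlandAltmanResult(**{**ba.__dict__, "adjusted_p": p_adj})
        try:
            ccc = lin_ccc(dev, ref)
        except ValueError:
            ccc = None
        return AgreementResults(
            model=self, keep_mask=keep, ape_values=ape,
            ape=summ, bland_altman=ba, concordance=ccc,
            params=dict(fence_k=fence_k, quartile_method=quartile_method,
                        bonferroni_m=bonferroni_m, alpha=alpha, loa_z=loa_z),
        )


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement statistics for one device/metric group."""

    model: DeviceAgreement
    keep_mask: np.ndarray = field(repr=False)
    ape_values: np.ndarray = field(repr=False)
    ape: ApeSummary
    bland_altman: BlandAltmanResult
    concordance: ConcordanceResult | None
    params: dict

    @property
    def n_removed(self) -> int:
        return int(self.keep_mask.size - self.keep_mask.sum())

    def summary(self) -> pd.DataFrame:
        """One-row table mirroring the study's report columns."""
        ba = self.bland_altman
        row = {
            "metric": self.model.metric,
            "device": self.model.label,
            "n": self.ape.n,
            "n_removed": self.n_removed,
            "mape_pct": self.ape.mape_pct,
            "min_pct": self.ape.min_pct,
            "median_pct": self.ape.median_pct,
            "max_pct": self.ape.max_pct,
            "iqr_pct": self.ape.iqr_pct,
            "bias": ba.bias,
            "bias_ci_low": ba.bias_ci[0],
            "bias_ci_high": ba.bias_ci[1],
            "adjusted_p": ba.adjusted_p,
            "lower_loa": ba.lower_loa,
            "upper_loa": ba.upper_loa,
            "loa_range": ba.loa_range,
            "ccc": self.concordance.ccc if self.concordance else np.nan,
        }
        return pd.DataFrame([row])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary().to_string(index=False)
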
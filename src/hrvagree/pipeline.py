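"""End-to-end validation runs: trials in, agreement report tables out.

Mirrors the published study flow: for each trial the reference RR series is
segmented to the trial's epoch, the reference metrics are computed (detrended
rMSSD, mean HR), the pair (device value, reference value) enters its
device/metric group, and each group runs the agreement chain — APE, Tukey
outer-fence removal, APE summary, Lin's CCC, Bland-Altman, Bonferroni-
corrected bias t-test.  Report writers emit one CSV per published table
schema plus a JSON bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrv
from .agreement import DeviceAgreement
from .ecg import segment_by_timestamps
from .series import RRSeries

__all__ = [
    "AnalysisConfig",
    "StudyDataset",
    "AgreementReport",
    "run_validation",
    "write_report",
    "load_trials",
]

logger = logging.getLogger("hrvagree")

VALID_EPOCHS_S = (180.0, 300.0)
TRIAL_COLUMNS = ["trial_id", "subject_id", "device_label", "metric",
                 "epoch_start_s", "epoch_s", "device_value", "units"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Every knob of the agreement chain, in one place.

    ``bonferroni_m`` of None means "use the number of devices present for
    the metric" (the study corrected within each metric family).
    ``round_reference`` compares integer device HR against integer
    reference HR instead of the raw reference value.
    """

    detrend: hrv.DetrendConfig = field(default_factory=hrv.DetrendConfig)
    detrend_rmssd: bool = True
    min_hr_window_s: float = 10.0
    fence_k: float = 3.0
    quartile_method: str = "linear"
    alpha: float = 0.05
    loa_z: float = 1.96
    bonferroni_m: int | None = None
    round_reference: bool = False
    hr_round_device_labels: tuple[str, ...] = ()


@dataclass
class StudyDataset:
    """Trial table plus per-trial reference data.

    ``trials`` has one row per (trial, metric) with the device's reported
    value; ``rr_series`` maps trial_id to the ground-truth/reference series.
    A trial may instead carry a raw ECG record in ``ecg_records``; its RR
    series is then obtained by R-peak detection at analysis time.
    """

    trials: pd.DataFrame
    rr_series: dict[int, RRSeries]
    ecg_records: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def resolve_reference(self, trial_id: int) -> RRSeries | None:
        rr = self.rr_series.get(trial_id)
        if rr is not None:
            return rr
        ecg = self.ecg_records.get(trial_id)
        if ecg is None:
            return None
        from .ecg import detect_r_peaks, extract_ibis

        rr, _gate = extract_ibis(detect_r_peaks(ecg))
        self.rr_series[trial_id] = rr  # cache the detection
        return rr

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rr_dir = out / "rr"
        rr_dir.mkdir(exist_ok=True)
        trials = self.trials.copy()
        trials["reference_path"] = [
            f"rr/trial_{tid:04d}.csv" for tid in trials["trial_id"]
        ]
        trials.to_csv(out / "trials.csv", index=False, float_format="%.17g")
        for tid, rr in self.rr_series.items():
            rr.to_csv(rr_dir / f"trial_{tid:04d}.csv")
        (out / "meta.json").write_text(json.dumps(self.meta, indent=2))


@dataclass
class AgreementReport:
    """Per device/metric agreement results plus run metadata."""

    groups: dict[tuple[str, str], "object"]  # (metric, device) -> results
    pairs: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def table(self, metric: str) -> pd.DataFrame:
        rows = [res.summary() for (m, _d), res in self.groups.items()
                if m == metric]
        if not rows:
            return pd.DataFrame()
        return pd.concat(rows, ignore_index=True)


def _reference_value(rr: RRSeries, metric: str, epoch_start_s: float,
                     epoch_s: float, cfg: AnalysisConfig) -> float:
    seg = segment_by_timestamps(rr, epoch_start_s, epoch_s)
    if metric == "HR":
        return hrv.mean_hr(seg)
    if metric == "rMSSD":
        detrend = cfg.detrend if cfg.detrend_rmssd and seg.rr_ms.size >= 3 \
            else None
        return hrv.rmssd(seg, detrend)
    raise ValueError(f"unknown metric {metric!r}")


def run_validation(dataset: StudyDataset,
                   config: AnalysisConfig = AnalysisConfig()
                   ) -> AgreementReport:
    """Run the full agreement analysis over a trial dataset.

    Deterministic given (dataset, config).  Per-group failures (e.g. a group
    emptied by removal) are recorded in the report metadata; the run
    continues with the remaining groups.
    """
    if dataset.trials.empty:
        raise ValueError("empty trial dataset")
    records = []
    errors: dict[str, str] = {}
    for row in dataset.trials.itertuples(index=False):
        rr = dataset.resolve_reference(row.trial_id)
        if rr is None:
            errors[f"trial {row.trial_id}"] = "unresolvable reference series"
            logger.warning("trial %s: no reference series", row.trial_id)
            continue
        ref = _reference_value(rr, row.metric, row.epoch_start_s,
                               row.epoch_s, config)
        if row.metric == "HR" and config.round_reference:
            ref = float(np.round(ref))
        records.append({
            "trial_id": row.trial_id, "subject_id": row.subject_id,
            "device_label": row.device_label, "metric": row.metric,
            "device_value": float(row.device_value),
            "reference_value": ref,
        })
        logger.info("trial %s %s/%s: device=%.3f reference=%.3f",
                    row.trial_id, row.device_label, row.metric,
                    row.device_value, ref)
    pairs = pd.DataFrame(records)
    groups: dict[tuple[str, str], object] = {}
    for metric, metric_df in pairs.groupby("metric", sort=False):
        m = config.bonferroni_m or metric_df["device_label"].nunique()
        for device, g in metric_df.groupby("device_label", sort=False):
            model = DeviceAgreement.from_dataframe(
                g, label=str(device), metric=str(metric))
            try:
                groups[(str(metric), str(device))] = model.fit(
                    fence_k=config.fence_k,
                    quartile_method=config.quartile_method,
                    bonferroni_m=int(m), alpha=config.alpha,
                    loa_z=config.loa_z,
                )
            except ValueError as exc:
                errors[f"{metric}/{device}"] = str(exc)
                logger.warning("group %s/%s failed: %s", metric, device, exc)
    meta = {
        "config": {
            "detrend_lambda": config.detrend.lambda_,
            "detrend_effective_fs_hz": config.detrend.effective_fs_hz,
            "detrend_rmssd": config.detrend_rmssd,
            "fence_k": config.fence_k,
            "quartile_method": config.quartile_method,
            "alpha": config.alpha,
            "loa_z": config.loa_z,
            "bonferroni_m": config.bonferroni_m,
            "round_reference": config.round_reference,
        },
        "dataset_meta": dataset.meta,
        "group_errors": errors,
    }
    return AgreementReport(groups=groups, pairs=pairs, meta=meta)


# ---------------------------------------------------------------------------
# report writers

def _fmt(x: float) -> str:
    """Fixed 2-decimal formatting; exact zeros render as '0'."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if x == 0:
        return "0"
    return f"{x:.2f}"


def _ape_table(report: AgreementReport, metric: str) -> pd.DataFrame:
    rows = []
    for (m, device), res in report.groups.items():
        if m != metric:
            continue
        a = res.ape
        rows.append({
            "Metric": metric, "Device": device, "n": a.n,
            "MAPE (%)": _fmt(a.mape_pct), "Min. (%)": _fmt(a.min_pct),
            "Median (%)": _fmt(a.median_pct), "Max. (%)": _fmt(a.max_pct),
            "IQR (%)": _fmt(a.iqr_pct),
            "_sort": a.mape_pct,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values("_sort").drop(columns="_sort").reset_index(drop=True)


def _ba_table(report: AgreementReport, metric: str) -> pd.DataFrame:
    rows = []
    for (m, device), res in report.groups.items():
        if m != metric:
            continue
        b = res.bland_altman
        rows.append({
            "Metric": metric, "Device": device, "n": b.n,
            "Bias (95% CI)": f"{_fmt(b.bias)} ({_fmt(b.bias_ci[0])}, "
                             f"{_fmt(b.bias_ci[1])})",
            "Adjusted p-value": _fmt(b.adjusted_p)
            if b.adjusted_p is not None else "NA",
            "Lower LOA (95% CI)": f"{_fmt(b.lower_loa)} "
                                  f"({_fmt(b.lower_loa_ci[0])}, "
                                  f"{_fmt(b.lower_loa_ci[1])})",
            "Upper LOA (95% CI)": f"{_fmt(b.upper_loa)} "
                                  f"({_fmt(b.upper_loa_ci[0])}, "
                                  f"{_fmt(b.upper_loa_ci[1])})",
            "LOA range": _fmt(b.loa_range),
            "_sort": b.loa_range,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values("_sort").drop(columns="_sort").reset_index(drop=True)


def _ccc_table(report: AgreementReport, metric: str = "rMSSD") -> pd.DataFrame:
    rows = []
    for (m, device), res in report.groups.items():
        if m != metric or res.concordance is None:
            continue
        rows.append({"Metric": metric, "Device": device,
                     "n": res.concordance.n,
                     "Concordance": _fmt(res.concordance.ccc),
                     "_sort": -res.concordance.ccc})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values("_sort").drop(columns="_sort").reset_index(drop=True)


def _json_groups(report: AgreementReport) -> dict:
    out = {}
    for (metric, device), res in report.groups.items():
        b = res.bland_altman
        out[f"{metric}/{device}"] = {
            "n": res.ape.n, "n_removed": res.n_removed,
            "mape_pct": res.ape.mape_pct, "min_pct": res.ape.min_pct,
            "median_pct": res.ape.median_pct, "max_pct": res.ape.max_pct,
            "iqr_pct": res.ape.iqr_pct,
            "bias": b.bias, "bias_ci": list(b.bias_ci),
            "adjusted_p": b.adjusted_p,
            "lower_loa": b.lower_loa, "lower_loa_ci": list(b.lower_loa_ci),
            "upper_loa": b.upper_loa, "upper_loa_ci": list(b.upper_loa_ci),
            "loa_range": b.loa_range, "sd_diff": b.sd_diff,
            "ccc": res.concordance.ccc if res.concordance else None,
        }
    return out


def write_report(report: AgreementReport, out_dir) -> list[Path]:
    """Write the report bundle: five table CSVs plus report.json.

    APE tables are sorted ascending by MAPE, Bland-Altman tables by LOA
    range; numbers are fixed 2-decimal with exact zeros rendered as '0'.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in [
        ("ape_hr.csv", _ape_table(report, "HR")),
        ("ape_rmssd.csv", _ape_table(report, "rMSSD")),
        ("ba_hr.csv", _ba_table(report, "HR")),
        ("ba_rmssd.csv", _ba_table(report, "rMSSD")),
        ("ccc_rmssd.csv", _ccc_table(report, "rMSSD")),
    ]:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
    payload = {"meta": report.meta, "groups": _json_groups(report)}
    path = out / "report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# ingestion

def load_trials(trials_csv, base_dir=None) -> StudyDataset:
    """Load a trial table (and its referenced RR series) from CSV.

    The table must carry the documented columns plus ``reference_path``
    pointing at two-column (beat_time_s, rr_ms) CSVs, resolved relative to
    the table's directory.  Validation failures name the offending row.
    """
    trials_csv = Path(trials_csv)
    base = Path(base_dir) if base_dir is not None else trials_csv.parent
    df = pd.read_csv(trials_csv, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if "reference_path" not in df.columns:
        raise ValueError("trial table missing 'reference_path' column")
    rr_series: dict[int, RRSeries] = {}
    for i, row in df.iterrows():
        if float(row["epoch_s"]) not in VALID_EPOCHS_S:
            raise ValueError(
                f"row {i}: epoch_s must be one of {VALID_EPOCHS_S}, "
                f"got {row['epoch_s']}"
            )
        if row["metric"] not in ("HR", "rMSSD"):
            raise ValueError(f"row {i}: unknown metric {row['metric']!r}")
        if pd.isna(row["reference_path"]):
            raise ValueError(f"row {i}: missing reference path")
        tid = int(row["trial_id"])
        if tid not in rr_series:
            path = base / str(row["reference_path"])
            if not path.exists():
                raise ValueError(f"row {i}: reference path {path} not found")
            rr_series[tid] = RRSeries.read_csv(path)
    meta = {}
    meta_path = base / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return StudyDataset(trials=df[TRIAL_COLUMNS + ["reference_path"]].copy(),
                        rr_series=rr_series, meta=meta)
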
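"""Cohort orchestration: per-scan-pair analysis, baseline fold-changes and
group summary tables."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import image_io
from .aeration import AerationReport, EmptyRegionError, aeration_report, tidal_volume
from .config import AnalysisConfig
from .core import CTVolume, LungLabelVolume, REGIONS, require_compatible
from .errors import (CalibrationError, DataError, RegistrationError,
                     SegmentationError)
from .registration import register_pair, warp_volume
from .segmentation import segment_lungs
from .ventilation import (VentilationThresholds, calibrate_thresholds,
                          classify_values, svg_arrays_for_pair,
                          CLASS_NORMAL, CLASS_LOW, CLASS_FIBROSIS, CLASS_MIXED)

log = logging.getLogger("pulmovent")

#: metrics carried into the fold-change table; %Fibrosis stays raw because
#: its baseline is ~0 and the ratio is unstable.
FOLD_CHANGE_METRICS = (
    "volume_p01", "volume_p02", "mla_p02", "pct_normo_p02", "pct_hypo_p02",
    "pct_non_p02", "pct_gas_p02", "tissue_volume_p02", "tidal_volume",
    "pct_normal_vent", "pct_low_vent",
)
RAW_METRICS = ("pct_fibrosis",)


@dataclass
class SubjectTimepointReport:
    """Every biomarker for one subject at one timepoint, per region."""

    subject_id: Optional[str]
    group: Optional[str]
    day: Optional[int]
    aeration: Dict[str, Dict[str, AerationReport]] = field(default_factory=dict)
    tidal_volumes: Dict[str, float] = field(default_factory=dict)
    ventilation: Optional[Dict[str, Dict[str, float]]] = None
    qc_flags: List[str] = field(default_factory=list)
    arrays: Optional[dict] = None  # lung-voxel SVg arrays, for calibration

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def metric(self, name: str, region: str = "whole") -> Optional[float]:
        """Look up a flat metric name like 'pct_normo_p02' or 'tidal_volume'."""
        if name == "tidal_volume":
            return self.tidal_volumes.get(region)
        if name.startswith("pct_") and name.endswith("_vent"):
            key = name[4:-5]
            if self.ventilation is None:
                return None
            return self.ventilation.get(region, {}).get(key)
        if name == "pct_fibrosis":
            if self.ventilation is None:
                return None
            return self.ventilation.get(region, {}).get("fibrosis")
        for phase_key in ("p01", "p02"):
            if name.endswith("_" + phase_key):
                base = name[: -len(phase_key) - 1]
                base = {"volume": "volume_mm3", "mla": "mla_hu",
                        "tissue_volume": "tissue_volume_mm3"}.get(base, base)
                rep = self.aeration.get(phase_key.upper(), {}).get(region)
                return getattr(rep, base, None) if rep else None
        return None

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "day": self.day,
            "qc_flags": list(self.qc_flags),
            "aeration": {
                phase: {region: rep.as_dict() for region, rep in by_region.items()}
                for phase, by_region in self.aeration.items()},
            "tidal_volumes": dict(self.tidal_volumes),
            "ventilation": self.ventilation,
        }


def _aeration_all_regions(ct, mask, boundaries) -> Dict[str, AerationReport]:
    out = {}
    for region in REGIONS:
        try:
            out[region] = aeration_report(ct, mask, region, boundaries)
        except EmptyRegionError:
            log.warning("empty region %s for subject=%s day=%s",
                        region, ct.subject_id, ct.day)
    return out


def _region_percentages(codes: np.ndarray, regions_flat: np.ndarray,
                        mixed_separate: bool) -> Dict[str, Dict[str, float]]:
    names = [("normal", CLASS_NORMAL), ("low", CLASS_LOW),
             ("fibrosis", CLASS_FIBROSIS)]
    if mixed_separate:
        names.append(("mixed", CLASS_MIXED))
    out = {}
    for region in REGIONS:
        if region == "whole":
            sel = np.ones(codes.shape, dtype=bool)
        else:
            sel = regions_flat == (1 if region == "left" else 2)
        sub = codes[sel]
        n = sub.size
        out[region] = {name: (100.0 * np.count_nonzero(sub == code) / n
                              if n else 0.0) for name, code in names}
    return out


def analyze_scan_pair(
    p01: CTVolume, p02: CTVolume, config: Optional[AnalysisConfig] = None,
    thresholds: Optional[VentilationThresholds] = None,
    mask_p01: Optional[LungLabelVolume] = None,
    mask_p02: Optional[LungLabelVolume] = None,
    keep_arrays: bool = True,
) -> SubjectTimepointReport:
    """Run the full per-pair pipeline: segment both phases, densitometry,
    register, warp, SVg/delta-SVg, classify.

    Stage failures become QC flags; the report is never silently partial —
    whatever stage failed is named in ``qc_flags`` and its metrics absent.
    Functional metrics are flagged absent when ``thresholds`` is None.
    """
    config = config or AnalysisConfig()
    report = SubjectTimepointReport(subject_id=p01.subject_id,
                                    group=None, day=p01.day)
    require_compatible(p01, p02, "scan pair")

    try:
        mask_p01 = mask_p01 or segment_lungs(p01, config.segmentation)
        mask_p02 = mask_p02 or segment_lungs(p02, config.segmentation)
    except SegmentationError as exc:
        log.warning("segmentation failed for subject=%s day=%s: %s",
                    p01.subject_id, p01.day, exc)
        report.qc_flags.append("segmentation-failure")
        return report

    report.aeration["P01"] = _aeration_all_regions(p01, mask_p01,
                                                   config.hu_boundaries)
    report.aeration["P02"] = _aeration_all_regions(p02, mask_p02,
                                                   config.hu_boundaries)
    for region in REGIONS:
        report.tidal_volumes[region] = tidal_volume(mask_p01, mask_p02, region)

    try:
        fieldv = register_pair(p01, p02, config.registration)
    except RegistrationError as exc:
        log.warning("registration failed for subject=%s day=%s: %s",
                    p01.subject_id, p01.day, exc)
        report.qc_flags.append("registration-failure")
        return report
    warped_p02 = warp_volume(p02, fieldv)
    warped_mask_p02 = warp_volume(mask_p02, fieldv)

    svg1, svg2, delta = svg_arrays_for_pair(
        p01, warped_p02, mask_p01.labels > 0, warped_mask_p02.labels > 0,
        config.tissue_specific_volume, config.hu_clip)
    valid = delta.mask
    if keep_arrays:
        report.arrays = {
            "svg1": svg1.values[valid].astype(np.float32),
            "svg2": svg2.values[valid].astype(np.float32),
            "delta": delta.values[valid].astype(np.float32),
            "region": mask_p01.labels[valid].astype(np.int8),
        }
    if thresholds is not None:
        attach_classification(report, thresholds, config)
    else:
        report.qc_flags.append("thresholds-absent")
    return report


def attach_classification(report: SubjectTimepointReport,
                          thresholds: VentilationThresholds,
                          config: AnalysisConfig) -> None:
    """Classify a previously analysed pair from its cached voxel arrays."""
    if report.arrays is None:
        raise CalibrationError("report carries no SVg arrays to classify")
    arr = report.arrays
    codes = classify_values(arr["svg1"], arr["svg2"], arr["delta"], thresholds,
                            config.mixed_class)
    report.ventilation = _region_percentages(
        codes, arr["region"], config.mixed_class == "separate")
    if "thresholds-absent" in report.qc_flags:
        report.qc_flags.remove("thresholds-absent")


def fold_change_vs_baseline(reports: Sequence[SubjectTimepointReport]) -> List[dict]:
    """Tidy fold-change rows for one subject against its day-0 report.

    Fold-change metrics are emitted as value/baseline; %Fibrosis is emitted
    raw. Subjects without a day-0 report yield no rows (logged).
    """
    reports = sorted(reports, key=lambda r: (r.day if r.day is not None else -1))
    baseline = next((r for r in reports if r.day == 0), None)
    if baseline is None:
        log.warning("subject %s has no day-0 report; excluded from fold-change",
                    reports[0].subject_id if reports else "?")
        return []
    rows: List[dict] = []
    for rep in reports:
        for region in REGIONS:
            for metric in FOLD_CHANGE_METRICS:
                value = rep.metric(metric, region)
                base = baseline.metric(metric, region)
                if value is None or base is None:
                    continue
                fc = value / base if base != 0 else float("nan")
                rows.append({"subject_id": rep.subject_id, "group": rep.group,
                             "day": rep.day, "region": region, "metric": metric,
                             "value": value, "baseline_value": base,
                             "fold_change": fc})
            for metric in RAW_METRICS:
                value = rep.metric(metric, region)
                if value is None:
                    continue
                rows.append({"subject_id": rep.subject_id, "group": rep.group,
                             "day": rep.day, "region": region, "metric": metric,
                             "value": value,
                             "baseline_value": baseline.metric(metric, region),
                             "fold_change": float("nan")})
    return rows


def summarize_group(table: pd.DataFrame, group: str, day: int, metric: str,
                    region: str = "whole", column: Optional[str] = None,
                    sem_single: str = "zero") -> Tuple[float, float, int]:
    """Mean, SEM (sd/sqrt(n), sd with n-1 denominator) and n for one cell.

    ``column`` defaults to 'fold_change' for fold-change metrics and
    'value' for raw metrics.
    """
    if column is None:
        column = "value" if metric in RAW_METRICS else "fold_change"
    sel = table[(table["group"] == group) & (table["day"] == day)
                & (table["metric"] == metric) & (table["region"] == region)]
    values = sel[column].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        raise ValueError(f"no data for {group}/{day}/{metric}/{region}")
    mean = float(values.mean())
    if n == 1:
        sem = float("nan") if sem_single == "nan" else 0.0
    else:
        sem = float(values.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


def _load_manifest(manifest_path) -> Tuple[pd.DataFrame, str]:
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "day", "p01_path", "p02_path"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise DataError(f"manifest missing columns: {sorted(missing_cols)}")
    root = os.path.dirname(os.path.abspath(manifest_path))
    missing = []
    for _, row in manifest.iterrows():
        for key in ("p01_path", "p02_path", "mask_path"):
            if key in manifest.columns and isinstance(row.get(key), str):
                path = os.path.join(root, row[key])
                if not os.path.exists(path):
                    missing.append(path)
    if missing:
        raise DataError("manifest references missing files:\n  "
                        + "\n  ".join(missing))
    return manifest, root


def run_cohort(manifest_path, config: Optional[AnalysisConfig] = None,
               out_dir: Optional[str] = None) -> dict:
    """Calibrate on day-0 scans, analyse every pair, write all tables.

    Returns paths of the outputs: per-subject report JSONs, the calibrated
    thresholds YAML, the tidy fold-change CSV and the group-summary CSV.
    Deterministic given identical inputs.
    """
    config = config or AnalysisConfig()
    out_dir = out_dir or config.output_dir or "pulmovent_out"
    manifest, root = _load_manifest(manifest_path)
    reports_dir = os.path.join(out_dir, "reports")
    os.makedirs(reports_dir, exist_ok=True)

    def load_pair(row):
        p01 = image_io.read_volume(os.path.join(root, row["p01_path"]), "P01",
                                   row["subject_id"], int(row["day"]))
        p02 = image_io.read_volume(os.path.join(root, row["p02_path"]), "P02",
                                   row["subject_id"], int(row["day"]))
        return p01, p02

    cal_groups = (set(config.calibration_groups)
                  if config.calibration_groups else set(manifest["group"]))
    if not (manifest["day"] == 0).any():
        raise DataError("manifest has no day-0 scans for calibration")

    reports: Dict[Tuple[str, int], SubjectTimepointReport] = {}
    basal_arrays = []
    for _, row in manifest.sort_values(["subject_id", "day"]).iterrows():
        key = (row["subject_id"], int(row["day"]))
        p01, p02 = load_pair(row)
        rep = analyze_scan_pair(p01, p02, config)
        rep.subject_id, rep.group, rep.day = row["subject_id"], row["group"], int(row["day"])
        reports[key] = rep
        if (int(row["day"]) == 0 and row["group"] in cal_groups
                and rep.arrays is not None):
            basal_arrays.append((rep.arrays["svg1"], rep.arrays["svg2"],
                                 rep.arrays["delta"]))
        log.info("analyzed subject=%s day=%s flags=%s", row["subject_id"],
                 row["day"], rep.qc_flags)

    if not basal_arrays:
        raise CalibrationError("no analysable day-0 scans for calibration")
    thresholds = calibrate_thresholds(
        basal_arrays, config.calibration_percentiles, config.calibration_mode,
        cohort_id=os.path.basename(str(manifest_path)))

    for rep in reports.values():
        if rep.arrays is not None:
            attach_classification(rep, thresholds, config)

    thresholds_path = os.path.join(out_dir, "thresholds.yaml")
    with open(thresholds_path, "w") as fh:
        yaml.safe_dump(thresholds.as_dict(), fh, sort_keys=False)

    for (subject, day), rep in sorted(reports.items()):
        with open(os.path.join(reports_dir, f"{subject}_day{day:02d}.json"),
                  "w") as fh:
            json.dump(rep.to_json_dict(), fh, indent=1, sort_keys=True)

    rows: List[dict] = []
    for subject in sorted(manifest["subject_id"].unique()):
        subject_reports = [rep for (s, _), rep in sorted(reports.items())
                           if s == subject]
        rows.extend(fold_change_vs_baseline(subject_reports))
    fold_table = pd.DataFrame(rows)
    fold_path = os.path.join(out_dir, "fold_change.csv")
    fold_table.to_csv(fold_path, index=False, float_format="%.10g")

    summary_rows = []
    if len(fold_table):
        for (group, day, region, metric), _ in fold_table.groupby(
                ["group", "day", "region", "metric"], sort=True):
            try:
                mean, sem, n = summarize_group(fold_table, group, day, metric,
                                               region,
                                               sem_single=config.sem_single)
            except ValueError:
                continue
            quantity = "value" if metric in RAW_METRICS else "fold_change"
            summary_rows.append({"group": group, "day": day, "region": region,
                                 "metric": metric, "quantity": quantity,
                                 "mean": mean, "sem": sem, "n": n})
    summary_path = os.path.join(out_dir, "group_summary.csv")
    pd.DataFrame(summary_rows).to_csv(summary_path, index=False,
                                      float_format="%.10g")
    return {"reports_dir": reports_dir, "thresholds": thresholds_path,
            "fold_change": fold_path, "group_summary": summary_path,
            "thresholds_obj": thresholds, "reports": reports,
            "fold_table": fold_table}
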
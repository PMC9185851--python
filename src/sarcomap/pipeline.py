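"""Per-patient and cohort-level orchestration.

A YAML manifest maps patients to visits to the files of that visit's
acquisitions (saturation-recovery, diffusion and dynamic series with their
sidecars, plus the tumour ROI); histology joins by patient ID from a
separate CSV, optionally complemented by a Ct table + panel from which
hypoxia scores are computed. Per-visit processing is:

1. T1 map from the saturation-recovery series (restricted to the ROI);
2. ADC map from the diffusion series;
3. iAUC60 map from the dynamic series using the T1 map as baseline T10;
4. ROI transfer to each map grid, in-plane erosion, then median/IQR
   summaries (tumour volume is taken from the uneroded outline).

Failures are isolated per stage and per visit: a corrupt series loses that
parameter for that visit, never the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (AcquisitionParams, ImageSeries, RoiMask, get_logger,
                   read_image_series, read_roi_mask, read_sidecar,
                   write_parameter_map)
from .dce import iauc60_map
from .diffusion import AdcFitOptions, fit_adc_map
from .hypoxia import ExpressionTable, read_ct_table, read_panel, score_all_samples
from .relaxometry import SrFitOptions, fit_t1_map
from .roi import EmptyRoiError, erode_roi, roi_volume_cm3, summarise_roi, transfer_roi
from .stats import build_table3, caix_stratification, compare_visits, validate_cohort

__all__ = ["run_patient_visit", "run_patient", "run_cohort", "load_manifest"]

log = get_logger(__name__)

_PARAMS = ("t1", "adc", "iauc60")


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or "patients" not in manifest or not manifest["patients"]:
        raise ValueError(f"manifest {path} lists no patients")
    return manifest


def _acq_from_sidecar(path: str | Path) -> AcquisitionParams:
    meta = read_sidecar(path)
    kwargs = {k: meta[k] for k in ("flip_angle_deg", "tr_ms", "te_ms",
                                   "relaxivity_r1", "baseline_frame_count")
              if k in meta}
    return AcquisitionParams(**kwargs)


def run_patient_visit(patient: str, visit: int, entry: dict,
                      out_dir: Path | None = None,
                      sr_options: SrFitOptions = SrFitOptions(),
                      adc_options: AdcFitOptions = AdcFitOptions()) -> dict:
    """Process one patient-visit: maps, ROI summaries, error bookkeeping.

    Returns a flat row dict (cohort CSV schema) plus an ``errors`` mapping
    of failed stages.
    """
    row: dict = {"patient": patient, "visit": int(visit)}
    errors: dict = {}

    roi = None
    try:
        roi = read_roi_mask(entry["roi"])
        row["volume_cm3"] = roi_volume_cm3(roi)
    except Exception as exc:  # noqa: BLE001 — per-stage isolation is the contract
        errors["roi"] = str(exc)
        log.error("%s v%d ROI failed: %s", patient, visit, exc)

    def _roi_on(series: ImageSeries) -> RoiMask:
        moved = transfer_roi(roi, series.geometry)
        return erode_roi(moved)

    t1_map = None
    sr_series = None
    if roi is not None:
        try:
            sr_series = read_image_series(entry["sr"], entry["sr_sidecar"])
            t1_map, _ = fit_t1_map(sr_series, sr_options,
                                   roi_mask=transfer_roi(roi, sr_series.geometry).mask)
            s = summarise_roi(t1_map, _roi_on(sr_series))
            row.update(t1_median=s.median, t1_iqr_low=s.iqr_low,
                       t1_iqr_high=s.iqr_high, t1_n_voxels=s.n_voxels)
            if out_dir is not None:
                write_parameter_map(t1_map, out_dir / f"{patient}_v{visit}_t1.nii.gz")
        except Exception as exc:  # noqa: BLE001
            errors["t1"] = str(exc)
            log.error("%s v%d T1 failed: %s", patient, visit, exc)

        try:
            dwi = read_image_series(entry["dwi"], entry["dwi_sidecar"])
            adc_map = fit_adc_map(dwi, adc_options)
            s = summarise_roi(adc_map, _roi_on(dwi))
            row.update(adc_median=s.median, adc_iqr_low=s.iqr_low,
                       adc_iqr_high=s.iqr_high, adc_n_voxels=s.n_voxels)
            if out_dir is not None:
                write_parameter_map(adc_map, out_dir / f"{patient}_v{visit}_adc.nii.gz")
        except Exception as exc:  # noqa: BLE001
            errors["adc"] = str(exc)
            log.error("%s v%d ADC failed: %s", patient, visit, exc)

        try:
            if t1_map is None:
                raise ValueError("no baseline T1 map (T1 stage failed)")
            dce = read_image_series(entry["dce"], entry["dce_sidecar"])
            acq = _acq_from_sidecar(entry["dce_sidecar"])
            roi_dyn = transfer_roi(roi, dce.geometry)
            imap = iauc60_map(dce, t1_map, acq, roi=roi_dyn)
            s = summarise_roi(imap, erode_roi(roi_dyn))
            row.update(iauc60_median=s.median, iauc60_iqr_low=s.iqr_low,
                       iauc60_iqr_high=s.iqr_high, iauc60_n_voxels=s.n_voxels)
            if out_dir is not None:
                write_parameter_map(imap, out_dir / f"{patient}_v{visit}_iauc60.nii.gz")
        except Exception as exc:  # noqa: BLE001
            errors["iauc60"] = str(exc)
            log.error("%s v%d iAUC60 failed: %s", patient, visit, exc)

    row["errors"] = errors
    return row


def run_patient(patient: str, patient_entry: dict,
                out_dir: Path | None = None, **kwargs) -> list[dict]:
    """All visits of one patient; missing visits are flagged, not fatal."""
    rows = []
    visits = patient_entry.get("visits", {})
    present = {int(v) for v in visits}
    for visit in sorted(present):
        rows.append(run_patient_visit(patient, int(visit), visits[visit],
                                      out_dir=out_dir, **kwargs))
    for visit in {1, 2, 3} - present:
        log.warning("%s: visit %d missing from manifest", patient, visit)
    return rows


def _join_histology(cohort: pd.DataFrame, manifest: dict) -> pd.DataFrame:
    hist = pd.read_csv(manifest["histology"])
    if "ct_table" in manifest and "panel" in manifest:
        sig, ctrl = read_panel(manifest["panel"])
        table = read_ct_table(manifest["ct_table"], sig, ctrl)
        scores = score_all_samples(table)
        hist = hist.merge(scores.rename("hypoxia_score"), left_on="patient",
                          right_index=True, how="left")
    return cohort.merge(hist, on="patient", how="left")


def run_cohort(manifest: str | Path | dict, out_dir: str | Path,
               **kwargs) -> dict:
    """Run every patient, assemble the cohort table and the statistics
    reports (correlation grid, visit tests, CAIX stratification).

    Writes ``cohort.csv``, ``table3.csv``, ``visit_tests.csv``,
    ``caix_stratification.csv`` and ``run_report.json`` under ``out_dir``.
    Outputs are deterministic functions of the inputs; patient order in the
    manifest does not affect any statistic.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    out = Path(out_dir)
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: dict = {}
    for patient in sorted(manifest["patients"]):
        prow = run_patient(patient, manifest["patients"][patient],
                           out_dir=maps_dir, **kwargs)
        for r in prow:
            errs = r.pop("errors", {})
            if errs:
                failures[f"{r['patient']}_v{r['visit']}"] = errs
        rows.extend(prow)
    if len({r["patient"] for r in rows}) < 3:
        raise ValueError("cohort run needs at least 3 patients")

    cohort = pd.DataFrame(rows).sort_values(["patient", "visit"]).reset_index(drop=True)
    if "histology" in manifest:
        cohort = _join_histology(cohort, manifest)
    cohort.to_csv(out / "cohort.csv", index=False)

    reports = {}
    try:
        validate_cohort(cohort)
        table3 = build_table3(cohort)
        table3.to_csv(out / "table3.csv", index=False)
        strat = caix_stratification(cohort)
        strat.to_csv(out / "caix_stratification.csv", index=False)
        reports["table3"] = table3
        reports["caix_stratification"] = strat
    except ValueError as exc:
        log.warning("statistics layer skipped: %s", exc)
        reports["stats_error"] = str(exc)

    visit_rows = []
    for param in ("t1_median", "adc_median", "iauc60_median", "volume_cm3"):
        if param not in cohort.columns:
            continue
        for va, vb in ((1, 2), (1, 3), (2, 3)):
            try:
                visit_rows.append(compare_visits(cohort, param, va, vb))
            except ValueError as exc:
                visit_rows.append({"parameter": param, "visit_a": va, "visit_b": vb,
                                   "p_value": np.nan, "error": str(exc)})
    visit_tests = pd.DataFrame(visit_rows)
    visit_tests.to_csv(out / "visit_tests.csv", index=False)
    reports["visit_tests"] = visit_tests

    report = {
        "software_version": __version__,
        "n_patients": int(cohort["patient"].nunique()),
        "n_rows": int(len(cohort)),
        "failures": failures,
        "outputs": ["cohort.csv", "table3.csv", "visit_tests.csv",
                    "caix_stratification.csv"],
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    reports["cohort"] = cohort
    reports["run_report"] = report
    return reports
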
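"""Subject- and cohort-level orchestration.

A subject folder holds ``he.tiff``, ``iba1.tiff``, ``gfap.tiff``, an MRI
counterpart with ``mri_NAWM.png`` / ``mri_WMH.png`` ROI masks and a
``landmarks.csv`` pairing MRI and HE points; the cohort folder holds one
such directory per subject plus ``cohort.csv``.

``run_cohort`` is two-pass: pass 1 prepares every subject (stain
separation, stain-to-HE registration, ROI transfer) and collects the
per-subject candidate mean ODs; the cohort-level threshold rule needs all
subjects before any segmentation, so pass 2 segments and measures with the
derived thresholds.  ``run_subject`` alone falls back to a provisional
per-subject threshold, flagged as such.  A missing or unreadable stain
skips that stain (or subject) with a logged error record; the cohort run
continues.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from . import cohort_stats as cs
from . import glial_quantification as gq
from . import perivascular_grading as pv
from .config import PipelineConfig, save_config
from .imaging_io import (cohort_to_dataframe, read_cohort_table, read_landmarks,
                         read_roi_masks, read_stain_image)
from .registration import (LandmarkSet, Transform2D, fit_landmark_transform,
                           register_intensity, transfer_rois, warp_image)
from .stain_separation import (default_hdab_vectors, separate_image,
                               vectors_from_config)
from .synthetic_cohort import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

STAIN_FILES = {"HE": "he.tiff", "IBA1_DAB": "iba1.tiff", "GFAP_DAB": "gfap.tiff"}


def _log_stage(stage: str, subject: str, t0: float, **scalars) -> None:
    extra = " ".join(f"{k}={v}" for k, v in scalars.items())
    logger.info("stage=%s subject=%s elapsed=%.2fs %s", stage, subject,
                time.monotonic() - t0, extra)


def _stain_vectors(config: PipelineConfig):
    if config.stain_vectors is None:
        return default_hdab_vectors()
    return vectors_from_config(config.stain_vectors)


def prepare_subject(config: PipelineConfig, subject_dir, subject_id: str | None = None) -> dict:
    """Pass 1: load, deconvolve, co-register stains and transfer ROIs.

    Returns hematoxylin/DAB maps on the HE grid, the transferred ROI set,
    per-stain candidate mean ODs for the cohort threshold, and a list of
    stains that had to be skipped.
    """
    subject_dir = Path(subject_dir)
    sid = subject_id or subject_dir.name
    px = config.working_pixel_size_um
    vectors = _stain_vectors(config)
    t0 = time.monotonic()

    he = read_stain_image(subject_dir / STAIN_FILES["HE"], config.scan_pixel_size_um,
                          "HE", subject_id=sid,
                          working_pixel_size_um=px)
    he_maps = separate_image(he, vectors)
    he_hema = he_maps["hematoxylin"]

    # MRI-drawn ROIs -> HE grid via landmarks
    lm_moving, lm_fixed = read_landmarks(subject_dir / "landmarks.csv")
    lm_result = fit_landmark_transform(LandmarkSet(lm_moving, lm_fixed),
                                       kind=config.landmark_kind)
    mri_paths = {name: subject_dir / f"mri_{name}.png" for name in ("NAWM", "WMH")
                 if (subject_dir / f"mri_{name}.png").exists()}
    roi_mri = read_roi_masks(mri_paths, grid="MRI", pixel_size_um=px)
    roi_set = transfer_rois(roi_mri, lm_result.transform, he_hema.shape, px)
    _log_stage("roi_transfer", sid, t0, rmse_px=f"{lm_result.rmse_px:.3f}")

    dab_maps = {}
    hema_maps = {"HE": he_hema}
    registrations = {}
    missing = []
    for stain in ("IBA1_DAB", "GFAP_DAB"):
        path = subject_dir / STAIN_FILES[stain]
        t1 = time.monotonic()
        try:
            img = read_stain_image(path, config.scan_pixel_size_um, stain,
                                   subject_id=sid, working_pixel_size_um=px)
            maps = separate_image(img, vectors)
        except (FileNotFoundError, ValueError, OSError) as exc:
            logger.warning("subject %s: stain %s skipped (%s)", sid, stain, exc)
            missing.append(stain)
            continue
        reg = register_intensity(maps["hematoxylin"], he_hema,
                                 metric=config.intensity_metric)
        if not reg.converged:
            # manual fallback stands in as identity here: sections are
            # reported unregistered and flagged for landmark entry
            logger.warning("subject %s: %s intensity registration failed; "
                           "needs manual landmarks", sid, stain)
            reg.transform = Transform2D.identity()
            reg.method = "manual_fallback"
        dab_maps[stain] = warp_image(maps["dab"], reg.transform, he_hema.shape)
        hema_maps[stain] = warp_image(maps["hematoxylin"], reg.transform,
                                      he_hema.shape)
        registrations[stain] = reg
        _log_stage("register", sid, t1, stain=stain, method=reg.method,
                   converged=reg.converged)

    roi_union = np.zeros(he_hema.shape, bool)
    for mask in roi_set.masks.values():
        roi_union |= mask
    candidate_means = {
        stain: gq.subject_candidate_mean(dab, roi_union)
        for stain, dab in dab_maps.items()
    }
    return {"subject_id": sid, "he": he, "he_hema": he_hema,
            "roi_set": roi_set, "dab_maps": dab_maps, "hema_maps": hema_maps,
            "registrations": registrations, "missing": missing,
            "candidate_means": candidate_means,
            "landmark_result": lm_result}


def _object_centroids(labels: np.ndarray) -> list:
    n = int(labels.max())
    if n == 0:
        return []
    centers = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    return [(c[1], c[0]) for c in centers]  # (x, y)


def quantify_subject(prep: dict, thresholds: dict, config: PipelineConfig) -> dict:
    """Pass 2: segment, measure cells, grade vessels for one prepared subject."""
    sid = prep["subject_id"]
    px = config.working_pixel_size_um
    roi_set = prep["roi_set"]
    region_rows, cell_rows, vessel_rows, summary_rows = [], [], [], []
    t0 = time.monotonic()

    gfap_full_labels = None
    gfap_full_mask = None
    if "GFAP_DAB" in prep["dab_maps"] and "GFAP_DAB" in thresholds:
        full = np.ones(prep["he_hema"].shape, bool)
        gfap_full_labels, gfap_full_mask = gq.segment_positive(
            prep["dab_maps"]["GFAP_DAB"], full,
            thresholds["GFAP_DAB"].threshold_od,
            config.min_object_area_um2, px)
    astro_centroids = (_object_centroids(gfap_full_labels)
                       if gfap_full_labels is not None else [])

    for stain, dab in prep["dab_maps"].items():
        thr = thresholds.get(stain)
        if thr is None:
            continue
        for roi_name, roi_mask in roi_set.masks.items():
            if not roi_mask.any():
                continue
            labels, mask = gq.segment_positive(dab, roi_mask, thr.threshold_od,
                                               config.min_object_area_um2, px)
            cells = gq.measure_all_cells(labels, dab, px, roi_name=roi_name)
            metrics = gq.region_metrics(cells, mask, dab, roi_mask, stain, sid,
                                        roi_name, px, od_max=config.od_max)
            region_rows.append(metrics.as_dict())
            if stain == "IBA1_DAB":
                for c in cells:
                    cell_rows.append({
                        "subject_id": sid, "roi_name": roi_name, "label": c.label,
                        "x": c.centroid_xy[0], "y": c.centroid_xy[1],
                        "area_um2": c.area_um2, "perimeter_um": c.perimeter_um,
                        "circularity": c.circularity,
                        "skeleton_length_um": c.skeleton_length_um,
                        "mean_od": c.mean_od})
    _log_stage("glia", sid, t0, n_regions=len(region_rows))

    # perivascular assessment: vessels on the HE hematoxylin map, astroglia
    # from the whole-frame GFAP segmentation
    t1 = time.monotonic()
    if gfap_full_mask is not None:
        for roi_name, roi_mask in roi_set.masks.items():
            if not roi_mask.any():
                continue
            vessels = pv.detect_vessels(prep["he_hema"], roi_mask, px,
                                        lumen_od_threshold=config.lumen_od_threshold,
                                        min_lumen_area_um2=config.min_lumen_area_um2,
                                        min_solidity=config.min_lumen_solidity,
                                        roi_name=roi_name)
            all_lumens = np.zeros(prep["he_hema"].shape, bool)
            for v in vessels:
                all_lumens |= v.lumen_mask
            assessments = []
            for v in vessels:
                others = all_lumens & ~v.lumen_mask
                assessment = pv.assess_vessel(
                    v, astro_centroids, px, gfap_positive_mask=gfap_full_mask,
                    other_lumens=others,
                    distance_um=config.perivascular_distance_um,
                    close_range_um=config.close_range_distance_um,
                    scar_kwargs={"angular_coverage": config.scar_angular_coverage,
                                 "area_fraction": config.scar_area_fraction})
                assessments.append(assessment)
                row = {"subject_id": sid, **assessment.__dict__}
                vessel_rows.append(row)
            if assessments:
                summary_rows.append(pv.summarize_region(assessments, sid,
                                                        roi_name).as_dict())
    _log_stage("perivascular", sid, t1, n_vessels=len(vessel_rows))

    return {"subject_id": sid, "region_metrics": region_rows,
            "cells": cell_rows, "vessels": vessel_rows,
            "vascular_summaries": summary_rows, "missing": prep["missing"]}


def _provisional_thresholds(prep: dict, config: PipelineConfig) -> dict:
    """Per-subject Otsu fallback when cohort thresholds are unavailable."""
    thresholds = {}
    for stain, mean in prep["candidate_means"].items():
        if mean is None:
            continue
        thresholds[stain] = gq.CohortThreshold(
            stain_kind=stain, threshold_od=config.kappa_threshold_factor * mean,
            per_subject_means=((prep["subject_id"], mean),),
            derivation="manual")
        logger.warning("subject %s: provisional per-subject threshold for %s",
                       prep["subject_id"], stain)
    return thresholds


def run_subject(config: PipelineConfig, subject_dir, thresholds: dict | None = None,
                write: bool = True) -> dict:
    """Run the full per-subject pipeline; see module docstring for stages."""
    prep = prepare_subject(config, subject_dir)
    if thresholds is None:
        thresholds = _provisional_thresholds(prep, config)
    result = quantify_subject(prep, thresholds, config)
    if write:
        out = Path(config.out_dir) / prep["subject_id"]
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(result["region_metrics"]).to_csv(out / "region_metrics.csv",
                                                      index=False)
        pd.DataFrame(result["cells"]).to_csv(out / "cells.csv", index=False)
        vr = [{k: v for k, v in row.items() if k != "lumen_mask"}
              for row in result["vessels"]]
        pd.DataFrame(vr).to_csv(out / "vessels.csv", index=False)
        pd.DataFrame(result["vascular_summaries"]).to_csv(
            out / "vascular_summary.csv", index=False)
        if config.qc_overlays:
            _write_qc_overlay(prep, out / "qc_rois.png")
    return result


def _write_qc_overlay(prep: dict, path) -> None:
    rgb = prep["he"].pixels.copy()
    colors = {"NAWM": (0, 160, 0), "WMH": (220, 0, 0)}
    for name, mask in prep["roi_set"].masks.items():
        edge = mask ^ ndimage.binary_erosion(mask)
        rgb[edge] = colors.get(name, (0, 0, 255))
    iio.imwrite(path, rgb)


def derive_thresholds(preps, config: PipelineConfig) -> dict:
    """Cohort-level thresholds from pass-1 candidate means (both stains)."""
    thresholds = {}
    for stain in ("IBA1_DAB", "GFAP_DAB"):
        per_subject = [(p["subject_id"], p["candidate_means"].get(stain))
                       for p in preps]
        per_subject = [(sid, m) for sid, m in per_subject if m is not None]
        if not per_subject:
            logger.warning("no %s candidates in any subject; stain skipped", stain)
            continue
        mean = float(np.mean([m for _, m in per_subject]))
        thresholds[stain] = gq.CohortThreshold(
            stain_kind=stain,
            threshold_od=config.kappa_threshold_factor * mean,
            per_subject_means=tuple(per_subject))
    return thresholds


def build_outcome_tables(region_df: pd.DataFrame, summary_df: pd.DataFrame,
                         records) -> dict:
    """Join measured outcomes to covariates, one wide table per family."""
    cov = cohort_to_dataframe(records)
    tables = {}
    for family, stain in (("microglia", "IBA1_DAB"), ("astroglia", "GFAP_DAB")):
        if len(region_df) == 0:
            continue
        sub = region_df[region_df.stain_kind == stain]
        if len(sub):
            tables[family] = sub.merge(cov, on="subject_id")
    if len(summary_df):
        tables["perivascular"] = summary_df.merge(cov, on="subject_id")
    return tables


def run_cohort(config: PipelineConfig) -> dict:
    """Run the whole cohort: two-pass quantification plus statistics."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_cohort_table(data_dir / "cohort.csv")

    preps, errors = [], []
    for rec in records:
        sdir = data_dir / rec.subject_id
        try:
            preps.append(prepare_subject(config, sdir, subject_id=rec.subject_id))
        except Exception as exc:  # noqa: BLE001 - cohort run must continue
            logger.error("subject %s failed in pass 1: %s", rec.subject_id, exc)
            errors.append({"subject_id": rec.subject_id, "stage": "prepare",
                           "error": str(exc)})

    thresholds = derive_thresholds(preps, config)
    results = []
    for prep in preps:
        try:
            results.append(quantify_subject(prep, thresholds, config))
        except Exception as exc:  # noqa: BLE001
            logger.error("subject %s failed in pass 2: %s", prep["subject_id"], exc)
            errors.append({"subject_id": prep["subject_id"], "stage": "quantify",
                           "error": str(exc)})

    region_df = pd.DataFrame([r for res in results for r in res["region_metrics"]])
    cells_df = pd.DataFrame([r for res in results for r in res["cells"]])
    summary_df = pd.DataFrame([r for res in results
                               for r in res["vascular_summaries"]])
    region_df.to_csv(out_dir / "region_metrics.csv", index=False)
    cells_df.to_csv(out_dir / "cells.csv", index=False)
    summary_df.to_csv(out_dir / "vascular_summaries.csv", index=False)

    # statistics (needs >= 2 subjects per group)
    counts = pd.Series([r.group for r in records]).value_counts()
    stats_results = []
    tables = build_outcome_tables(region_df, summary_df, records)
    if counts.min() >= 2 and len(counts) == 2:
        for family, outcomes in cs.DEFAULT_FAMILIES.items():
            if family not in tables:
                continue
            stats_results.extend(cs.run_family(tables[family], family, outcomes,
                                               mode="group_roi"))
            table = tables[family]
            if table["fazekas"].nunique() > 1 and \
                    np.unique(table["fazekas"] <= 1).size == 2:
                stats_results.extend(cs.run_family(table, family, outcomes,
                                                   mode="burden"))
        demo = cs.demographics_table(records)
        demo.to_csv(out_dir / "demographics.csv", index=False)
    else:
        logger.warning("fewer than 2 subjects per group; statistics skipped")

    stats_df = cs.results_frame(stats_results) if stats_results else pd.DataFrame()
    stats_df.to_csv(out_dir / "stats_results.csv", index=False)
    report = render_report(region_df, summary_df, stats_df, records)
    (out_dir / "report.txt").write_text(report)
    save_config(config, out_dir / "config.yaml")
    manifest = {
        "n_subjects": len(records), "n_processed": len(results),
        "errors": errors,
        "thresholds": {k: v.threshold_od for k, v in thresholds.items()},
        "outputs": ["region_metrics.csv", "cells.csv", "vascular_summaries.csv",
                    "stats_results.csv", "report.txt", "config.yaml"],
        "bonferroni_families": {k: len(v) for k, v in cs.DEFAULT_FAMILIES.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"region_metrics": region_df, "cells": cells_df,
            "vascular_summaries": summary_df, "stats": stats_df,
            "thresholds": thresholds, "errors": errors, "tables": tables,
            "records": records}


def _fmt_cell(df, group, roi, col):
    sub = df[(df.group == group) & (df.roi_name == roi)][col].astype(float)
    sub = sub.dropna()
    if len(sub) == 0:
        return "-"
    return f"{sub.mean():8.2f} +/- {sub.std(ddof=1):6.2f}"


def render_report(region_df, summary_df, stats_df, records) -> str:
    """Text report: outcome means by group x ROI with corrected p values."""
    cov = cohort_to_dataframe(records)[["subject_id", "group"]]
    lines = ["Neurovascular inflammation by group and region", "=" * 78]
    blocks = []
    if len(region_df):
        merged = region_df.merge(cov, on="subject_id")
        blocks.append(("Microglia (IBA1)", merged[merged.stain_kind == "IBA1_DAB"],
                       ["frequency_per_mm2", "area_pct", "intensity_pct",
                        "avg_length_um", "avg_circularity"]))
        blocks.append(("Astroglia (GFAP)", merged[merged.stain_kind == "GFAP_DAB"],
                       ["area_pct", "intensity_pct"]))
    if len(summary_df):
        blocks.append(("Perivascular inflammation", summary_df.merge(cov, on="subject_id"),
                       ["pct_with_inflammation", "pct_mild", "pct_moderate",
                        "pct_severe", "pct_close_range"]))
    p_lookup = {}
    if len(stats_df):
        for _, row in stats_df.iterrows():
            p_lookup[(row["outcome_name"], row["effect"])] = row["p_bonferroni"]
    for title, df, cols in blocks:
        if len(df) == 0:
            continue
        lines.append("")
        lines.append(title)
        header = f"{'outcome':<22}" + "".join(
            f"{g[:4]}/{r:<5}".rjust(20)
            for g in ("control", "hypertension") for r in ("NAWM", "WMH"))
        lines.append(header + "   p(group)   p(roi)")
        for col in cols:
            row = f"{col:<22}"
            for g in ("control", "hypertension"):
                for r in ("NAWM", "WMH"):
                    row += _fmt_cell(df, g, r, col).rjust(20)
            pg = p_lookup.get((col, "group"))
            pr = p_lookup.get((col, "roi"))
            row += f"   {pg:.3f}" if pg is not None else "   -"
            row += f"   {pr:.3f}" if pr is not None else "   -"
            lines.append(row)
    return "\n".join(lines) + "\n"


def make_demo(out_dir, n_hypertension: int = 17, n_control: int = 5,
              seed: int = 0, **spec_kwargs) -> dict:
    """Generate a ready-to-run synthetic cohort in ``out_dir``."""
    spec = CohortSpec(n_hypertension=n_hypertension, n_control=n_control,
                      seed=seed, **spec_kwargs)
    return generate_cohort(spec, out_dir)
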
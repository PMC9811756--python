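"""Segmentation and morphometrics of DAB-positive glia within ROIs.

Microglia (IBA1) and astroglia (GFAP) are segmented from the DAB
concentration map by a cohort-level optical-density threshold and measured
per object.  Morphometric read-outs follow the activation biology: resting
microglia are ramified (low circularity, long skeleton), activated microglia
amoeboid (circularity near 1, short skeleton).  Per-region outcomes are:

* frequency — positive cells per mm^2 of ROI;
* area (%) — positive pixel fraction of the ROI;
* intensity (%) — mean positive-pixel DAB OD as a percentage of ``od_max``;
* average length (µm) — mean skeleton length over cells;
* circularity — mean of ``4*pi*area / perimeter**2`` over cells.

GFAP astroglia frequently fuse into scars, so per-cell outcomes (frequency,
length, circularity) are suppressed for that stain and only area/intensity
are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)

#: default factor applied to the cohort mean positive-cell OD; half the mean
#: approximates the positive/background boundary (reconstruction, config-exposed)
DEFAULT_KAPPA = 0.5
#: debris filter, below microglial soma scale (reconstruction, config-exposed)
DEFAULT_MIN_OBJECT_AREA_UM2 = 20.0
#: OD ceiling used to express mean positive OD as a percentage
DEFAULT_OD_MAX = 2.0

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class CohortThreshold:
    """Cohort-level DAB OD cutoff, derived from per-subject candidate means."""

    stain_kind: str
    threshold_od: float
    per_subject_means: tuple  # ((subject_id, mean_od), ...) kept for QC
    derivation: str = "cohort_mean"

    def __post_init__(self) -> None:
        if not self.threshold_od > 0:
            raise ValueError("threshold_od must be positive")
        if len(self.per_subject_means) < 1:
            raise ValueError("threshold must derive from at least one subject")


@dataclass(frozen=True)
class CellObject:
    """Morphometrics of one segmented glial cell."""

    label: int
    centroid_xy: tuple
    area_um2: float
    perimeter_um: float
    circularity: float
    skeleton_length_um: float
    mean_od: float
    roi_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.circularity <= 1.0):
            raise ValueError("circularity must lie in [0, 1]")


@dataclass(frozen=True)
class RegionMetrics:
    """Per (subject x ROI x stain) outcome vector."""

    subject_id: str
    roi_name: str
    stain_kind: str
    frequency_per_mm2: float
    area_pct: float
    intensity_pct: float
    avg_length_um: float
    avg_circularity: float
    n_objects: int

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "roi_name": self.roi_name,
            "stain_kind": self.stain_kind,
            "frequency_per_mm2": self.frequency_per_mm2,
            "area_pct": self.area_pct,
            "intensity_pct": self.intensity_pct,
            "avg_length_um": self.avg_length_um,
            "avg_circularity": self.avg_circularity,
            "n_objects": self.n_objects,
        }


# ---------------------------------------------------------------------------
# cohort-level thresholding
# ---------------------------------------------------------------------------

def subject_candidate_mean(dab_map: np.ndarray, roi_mask: np.ndarray) -> float | None:
    """Mean OD of positive-candidate pixels inside the ROI (Otsu cut).

    Returns None when the ROI is empty or Otsu finds no positive pixels.
    """
    values = np.asarray(dab_map, float)[np.asarray(roi_mask, bool)]
    if values.size == 0 or np.ptp(values) < 1e-12:
        return None
    cut = threshold_otsu(values)
    positive = values[values >= cut]
    if positive.size == 0:
        return None
    return float(positive.mean())


def derive_cohort_threshold(dab_maps_by_subject, roi_sets_by_subject,
                            stain_kind: str, kappa: float = DEFAULT_KAPPA) -> CohortThreshold:
    """Cohort OD threshold: ``kappa`` x mean over subjects of the candidate mean.

    Per subject, candidate positives are found by an automatic (Otsu) cut on
    in-ROI DAB OD and their mean OD recorded; the cohort threshold is the
    mean of those per-subject means scaled by ``kappa``.  Per-subject means
    are retained so individual slides can be checked against the cohort rule.
    """
    per_subject = []
    for subject_id, dab_map in dab_maps_by_subject.items():
        roi_set = roi_sets_by_subject[subject_id]
        union = np.zeros(dab_map.shape, bool)
        for mask in roi_set.masks.values():
            union |= mask
        mean = subject_candidate_mean(dab_map, union)
        if mean is not None:
            per_subject.append((subject_id, mean))
    if not per_subject:
        raise ValueError("no positive candidates found in any subject")
    threshold = kappa * float(np.mean([m for _, m in per_subject]))
    return CohortThreshold(stain_kind=stain_kind, threshold_od=threshold,
                           per_subject_means=tuple(per_subject))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_positive(dab_map: np.ndarray, roi_mask: np.ndarray, threshold: float,
                     min_object_area_um2: float = DEFAULT_MIN_OBJECT_AREA_UM2,
                     pixel_size_um: float = 1.0,
                     max_hole_area_um2: float = 40.0):
    """Threshold, hole-fill and label DAB-positive objects inside an ROI.

    ``mask = (dab >= threshold) & roi`` with 8-connected components; holes up
    to soma scale (``max_hole_area_um2``) are filled — larger enclosures,
    e.g. between crossing ramifications of neighbouring cells, are left open
    so they do not inflate the stained area.  Components smaller than
    ``min_object_area_um2`` are removed (objects exactly at the limit are
    kept).  Cells straddling the ROI edge are clipped to the ROI.  Returns
    ``(labels, mask)``.
    """
    dab = np.asarray(dab_map, float)
    roi = np.asarray(roi_mask, bool)
    if dab.shape != roi.shape:
        raise ValueError("dab map and ROI mask shapes differ")
    mask = (dab >= threshold) & roi
    holes = ndimage.binary_fill_holes(mask) & ~mask
    hole_labels, n_holes = ndimage.label(holes)
    if n_holes:
        max_hole_px = max_hole_area_um2 / pixel_size_um ** 2
        sizes = np.bincount(hole_labels.ravel())
        small = sizes <= max_hole_px
        small[0] = False
        mask = (mask | small[hole_labels]) & roi
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n:
        min_px = min_object_area_um2 / (pixel_size_um ** 2)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_px
        keep[0] = False
        mask = keep[labels]
        labels, _ = ndimage.label(mask, structure=_EIGHT)
    return labels, mask


# ---------------------------------------------------------------------------
# per-object morphometrics
# ---------------------------------------------------------------------------

def _object_perimeter(mask: np.ndarray) -> float:
    """Boundary length by the Crofton formula (4 directions).

    Chain-code polygon length through boundary-pixel centres systematically
    overestimates smooth boundaries (a rasterised disk would read ~5% long,
    biasing circularity low); the Crofton estimator is unbiased for smooth
    shapes, keeping disk circularity at 1 within rasterisation error.
    """
    return float(measure.perimeter_crofton(np.pad(mask, 1), directions=4))


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Polyline length of a 1-px skeleton: orthogonal steps + sqrt(2) diagonals.

    A diagonal step is only counted when it is not shortcut by an orthogonal
    neighbour pair, so thick corners are not double counted.
    """
    sk = np.asarray(skeleton, bool)
    n_orth = int(np.count_nonzero(sk[:, :-1] & sk[:, 1:]))
    n_orth += int(np.count_nonzero(sk[:-1, :] & sk[1:, :]))
    # diagonal edges p -> p+(1,1) and p -> p+(1,-1)
    n_diag = 0
    se = sk[:-1, :-1] & sk[1:, 1:]
    redundant = sk[:-1, 1:] | sk[1:, :-1]
    n_diag += int(np.count_nonzero(se & ~redundant[: se.shape[0], : se.shape[1]]))
    sw = sk[:-1, 1:] & sk[1:, :-1]
    redundant2 = sk[:-1, :-1] | sk[1:, 1:]
    n_diag += int(np.count_nonzero(sw & ~redundant2))
    return n_orth + math.sqrt(2.0) * n_diag


def measure_cell(object_mask: np.ndarray, dab_map: np.ndarray,
                 pixel_size_um: float, label: int = 0,
                 roi_name: str = "") -> CellObject:
    """Morphometrics of one connected component.

    Area is the pixel count times the pixel area; the perimeter is the
    Crofton boundary-length estimate; circularity ``4*pi*A/P**2`` is clamped to 1
    (single pixels and rasterisation can push it above); skeleton length is
    the step-weighted length of the morphological thinning.
    """
    mask = np.asarray(object_mask, bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty object")
    area_um2 = n_px * pixel_size_um ** 2
    perimeter_px = _object_perimeter(mask)
    if perimeter_px > 0:
        circ = 4.0 * math.pi * n_px / perimeter_px ** 2
    else:
        circ = 1.0
    circ = min(circ, 1.0)
    sk = skeletonize(mask)
    length_um = skeleton_length_px(sk) * pixel_size_um
    ys, xs = np.nonzero(mask)
    mean_od = float(np.asarray(dab_map, float)[mask].mean())
    return CellObject(label=label,
                      centroid_xy=(float(xs.mean()), float(ys.mean())),
                      area_um2=float(area_um2),
                      perimeter_um=float(perimeter_px * pixel_size_um),
                      circularity=float(circ),
                      skeleton_length_um=float(length_um),
                      mean_od=mean_od,
                      roi_name=roi_name)


def measure_all_cells(labels: np.ndarray, dab_map: np.ndarray,
                      pixel_size_um: float, roi_name: str = "") -> list:
    cells = []
    n = int(labels.max())
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        sub = labels[sl] == lab
        cell = measure_cell(sub, np.asarray(dab_map)[sl], pixel_size_um,
                            label=lab, roi_name=roi_name)
        # shift centroid back to full-image coordinates
        cell = CellObject(label=cell.label,
                          centroid_xy=(cell.centroid_xy[0] + sl[1].start,
                                       cell.centroid_xy[1] + sl[0].start),
                          area_um2=cell.area_um2,
                          perimeter_um=cell.perimeter_um,
                          circularity=cell.circularity,
                          skeleton_length_um=cell.skeleton_length_um,
                          mean_od=cell.mean_od,
                          roi_name=cell.roi_name)
        cells.append(cell)
    return cells


# ---------------------------------------------------------------------------
# per-region outcomes
# ---------------------------------------------------------------------------

def region_metrics(cells, binary_mask: np.ndarray, dab_map: np.ndarray,
                   roi_mask: np.ndarray, stain_kind: str, subject_id: str,
                   roi_name: str, pixel_size_um: float,
                   od_max: float = DEFAULT_OD_MAX) -> RegionMetrics:
    """Aggregate segmented cells into the per-region outcome vector.

    For GFAP, per-cell outcomes (frequency, length, circularity) are reported
    as NaN: astroglia commonly merge into scars, so object counts are not
    meaningful for that stain.
    """
    roi = np.asarray(roi_mask, bool)
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise ValueError("empty ROI")
    mask = np.asarray(binary_mask, bool) & roi
    roi_area_mm2 = roi_px * (pixel_size_um / 1000.0) ** 2
    pos_px = int(mask.sum())
    area_pct = 100.0 * pos_px / roi_px
    if pos_px:
        intensity_pct = 100.0 * float(np.asarray(dab_map, float)[mask].mean()) / od_max
    else:
        intensity_pct = 0.0
    intensity_pct = float(np.clip(intensity_pct, 0.0, 100.0))
    n_objects = len(cells)
    if stain_kind == "GFAP_DAB":
        freq = length = circ = float("nan")
    else:
        freq = n_objects / roi_area_mm2
        length = float(np.mean([c.skeleton_length_um for c in cells])) if cells else float("nan")
        circ = float(np.mean([c.circularity for c in cells])) if cells else float("nan")
    return RegionMetrics(subject_id=subject_id, roi_name=roi_name,
                         stain_kind=stain_kind, frequency_per_mm2=freq,
                         area_pct=area_pct, intensity_pct=intensity_pct,
                         avg_length_um=length, avg_circularity=circ,
                         n_objects=n_objects)
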
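"""Synthetic white-matter cohort with full ground truth.

Generates paired "MRI" and brightfield histology data for a cohort of
subjects split into hypertension and control groups: HE, IBA1 and GFAP
slides rendered through the Beer-Lambert forward model (the exact inverse of
the package's colour deconvolution), binary NAWM/WMH ROI masks, a degraded
MRI counterpart with a known MRI-to-histology transform and exact landmark
pairs, and a metadata table.  Every rendered object is recorded in a
ground-truth structure, so each downstream stage (deconvolution,
registration, segmentation, morphometrics, perivascular grading, statistics)
can be validated against known values.

Group and region effects are realised through object placement: microglial
activation raises the amoeboid fraction and per-cell DAB amount and shortens
branches; astrogliosis raises astroglial density and DAB amount; perivascular
inflammation raises astroglial density in the 15 µm annulus around vessels
and the probability of an encircling scar.  Default effect directions follow
the hypertension > control and WMH > NAWM pattern of the study design the
generator emulates; magnitudes are free parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .imaging_io import (RoiSet, StainImage, SubjectRecord, cohort_to_dataframe,
                         mask_area_mm2, write_landmarks, write_mask,
                         write_stain_image)
from .perivascular_grading import grade_vessel
from .registration import Transform2D
from .stain_separation import StainVectors, default_hdab_vectors, od_to_rgb

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# object specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """One glial cell to render: soma disk plus radial branch arms."""

    center_xy: tuple  # pixel coordinates (x, y)
    phenotype: str  # "ramified" | "amoeboid" | "astro_star"
    soma_radius_um: float
    n_branches: int
    branch_length_um: float
    stain_amount: float  # DAB optical density added per drawn pixel
    orientation_rad: float = 0.0
    branch_width_px: int = 2

    def __post_init__(self) -> None:
        if not self.soma_radius_um > 0:
            raise ValueError("soma_radius_um must be positive")
        if self.phenotype == "ramified" and self.n_branches < 2:
            raise ValueError("ramified cells need at least 2 branches")
        if self.phenotype == "amoeboid" and self.n_branches != 0:
            raise ValueError("amoeboid cells have no branches")
        if self.stain_amount < 0:
            raise ValueError("negative stain amount")


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: elliptical lumen, wall, and a perivascular astroglia target."""

    center_xy: tuple
    lumen_axes_um: tuple  # semi-axes (a, b)
    orientation_rad: float = 0.0
    wall_thickness_um: float = 8.0
    perivascular_density_per_mm2: float = 0.0
    scar: bool = False

    def __post_init__(self) -> None:
        a, b = self.lumen_axes_um
        if not (a > 0 and b > 0):
            raise ValueError("lumen semi-axes must be positive")
        if self.perivascular_density_per_mm2 < 0:
            raise ValueError("perivascular density must be nonnegative")


def _effects(baseline, group_delta, roi_delta, sd, age_coef=0.0, fix_coef=0.0,
             burden_delta=0.0):
    return {"baseline": baseline, "group_delta": group_delta,
            "roi_delta": roi_delta, "sd": sd, "age_coef": age_coef,
            "fix_coef": fix_coef, "burden_delta": burden_delta}


def default_effects() -> dict:
    """Outcome-generating model defaults (hypertension > control, WMH > NAWM)."""
    return {
        # microglia (IBA1)
        "iba1_frequency_per_mm2": _effects(270.0, 15.0, 80.0, 40.0, age_coef=1.0,
                                           fix_coef=-0.5, burden_delta=30.0),
        "iba1_amoeboid_fraction": _effects(0.30, 0.12, 0.12, 0.05, age_coef=0.002),
        "iba1_stain_od": _effects(0.75, 0.06, 0.06, 0.05, burden_delta=0.03),
        "iba1_branch_length_um": _effects(22.0, -2.0, -3.0, 2.0),
        # astroglia (GFAP)
        "gfap_density_per_mm2": _effects(250.0, 60.0, 120.0, 50.0),
        "gfap_stain_od": _effects(0.70, 0.08, 0.08, 0.06),
        # perivascular astrogliosis
        "peri_density_per_mm2": _effects(150.0, 50.0, 70.0, 40.0),
        "scar_probability": _effects(0.03, 0.05, 0.07, 0.0),
    }


def scaled_effects(scale_group: float, scale_roi: float | None = None) -> dict:
    """Effect table with group (and optionally ROI) deltas scaled.

    ``scaled_effects(0.0)`` is the null cohort (no group effects);
    ``scaled_effects(3.0)`` is the large-delta setting where every group
    contrast is far outside the subject noise.
    """
    if scale_roi is None:
        scale_roi = 1.0
    eff = default_effects()
    for e in eff.values():
        e["group_delta"] *= scale_group
        e["roi_delta"] *= scale_roi
        e["burden_delta"] *= scale_group
    return eff


@dataclass
class CohortSpec:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated design: 17 hypertension vs 5 control
    subjects, 1 µm/px working resolution, two rectangular white-matter ROIs
    (NAWM and WMH) per subject, three vessels per ROI, and a degraded MRI
    counterpart 8x coarser than histology with a known affine.
    """

    n_hypertension: int = 17
    n_control: int = 5
    seed: int = 0
    pixel_size_um: float = 1.0
    slide_shape: tuple = (640, 640)
    effects: dict = field(default_factory=default_effects)
    # render / noise parameters
    noise_sd: float = 0.02  # additive OD noise on concentration maps
    texture_amp: float = 0.05  # smooth hematoxylin background texture
    hema_background: float = 0.30
    background_i0: float = 255.0
    # cell geometry
    microglia_soma_um: float = 3.5
    microglia_branches: int = 5
    astro_soma_um: float = 3.0
    astro_branches: int = 5
    astro_branch_um: float = 6.0
    # vessels
    vessels_per_roi: int = 3
    lumen_radius_range_um: tuple = (25.0, 45.0)
    # stain-section misalignment recovered by intensity registration
    stain_shift_px: float = 5.0
    # MRI counterpart
    mri_downsample: int = 8
    mri_rotation_deg_range: tuple = (-10.0, 10.0)
    mri_scale_range: tuple = (0.95, 1.05)
    mri_blur_px: float = 1.5
    n_landmarks: int = 12

    def __post_init__(self) -> None:
        if self.n_hypertension < 1 or self.n_control < 1:
            raise ValueError("group counts must be >= 1")
        for name, eff in self.effects.items():
            if eff["sd"] < 0:
                raise ValueError(f"{name}: noise SD must be nonnegative")


# ---------------------------------------------------------------------------
# rendering (Beer-Lambert forward model)
# ---------------------------------------------------------------------------

def _draw_thick_line(canvas: np.ndarray, r0, c0, r1, c1, width: int, amount: float):
    rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    h, w = canvas.shape
    offsets = [(0, 0)]
    if width >= 2:
        # offset perpendicular to the dominant direction
        if abs(r1 - r0) >= abs(c1 - c0):
            offsets.append((0, 1))
        else:
            offsets.append((1, 0))
    for dr, dc in offsets:
        rs, cs = rr + dr, cc + dc
        ok = (rs >= 0) & (rs < h) & (cs >= 0) & (cs < w)
        canvas[rs[ok], cs[ok]] = np.maximum(canvas[rs[ok], cs[ok]], amount)


def draw_cell_mask(cell: CellSpec, shape, pixel_size_um: float) -> np.ndarray:
    """Rasterise one cell (soma + branches) onto an amount canvas.

    Returns a float canvas holding ``stain_amount`` on cell pixels, 0
    elsewhere; branch/soma overlap is not double counted.
    """
    canvas = np.zeros(shape, float)
    x, y = cell.center_xy
    r_px = cell.soma_radius_um / pixel_size_um
    h, w = shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"cell centre {cell.center_xy} outside raster {shape}")
    rr, cc = draw_disk((y, x), max(r_px, 1.0), shape=shape)
    canvas[rr, cc] = cell.stain_amount
    if cell.n_branches:
        blen = cell.branch_length_um / pixel_size_um
        for k in range(cell.n_branches):
            ang = cell.orientation_rad + 2 * math.pi * k / cell.n_branches
            r0 = y + (r_px - 1) * math.sin(ang)
            c0 = x + (r_px - 1) * math.cos(ang)
            r1 = y + (r_px + blen) * math.sin(ang)
            c1 = x + (r_px + blen) * math.cos(ang)
            if not (0 <= r1 < h and 0 <= c1 < w):
                raise ValueError("cell branch extends outside raster")
            _draw_thick_line(canvas, r0, c0, r1, c1, cell.branch_width_px,
                             cell.stain_amount)
    return canvas


def vessel_lumen_mask(vessel: VesselSpec, shape, pixel_size_um: float) -> np.ndarray:
    a_px = vessel.lumen_axes_um[0] / pixel_size_um
    b_px = vessel.lumen_axes_um[1] / pixel_size_um
    x, y = vessel.center_xy
    mask = np.zeros(shape, bool)
    rr, cc = draw_ellipse(y, x, b_px, a_px, shape=shape,
                          rotation=vessel.orientation_rad)
    mask[rr, cc] = True
    return mask


def build_concentration_maps(cells, vessels, shape, pixel_size_um: float,
                             hema_background: float = 0.30,
                             texture: np.ndarray | None = None,
                             noise_sd: float = 0.0,
                             scar_band_um: float = 10.0,
                             scar_amount: float = 0.9,
                             rng: np.random.Generator | None = None) -> dict:
    """Assemble hematoxylin / DAB concentration maps for one slide."""
    rng = rng or np.random.default_rng(0)
    hema = np.full(shape, float(hema_background))
    if texture is not None:
        hema = np.maximum(hema + texture, 0.0)
    dab = np.zeros(shape, float)
    for cell in cells:
        dab += draw_cell_mask(cell, shape, pixel_size_um)
    lumens = np.zeros(shape, bool)
    for vessel in vessels:
        lumen = vessel_lumen_mask(vessel, shape, pixel_size_um)
        lumens |= lumen
        dist = ndimage.distance_transform_edt(~lumen) * pixel_size_um
        wall = (dist > 0) & (dist <= vessel.wall_thickness_um)
        hema[wall] += 0.35
        if vessel.scar:
            band = (dist > 0) & (dist <= scar_band_um)
            dab[band] += scar_amount
    hema[lumens] = 0.0
    dab[lumens] = 0.0
    if noise_sd > 0:
        hema = np.maximum(hema + rng.normal(0.0, noise_sd, shape), 0.0)
        dab = np.maximum(dab + rng.normal(0.0, noise_sd, shape), 0.0)
    return {"hematoxylin": hema, "dab": dab, "lumens": lumens}


def smooth_texture(shape, amplitude: float, rng: np.random.Generator,
                   sigma_px: float = 12.0) -> np.ndarray:
    """Low-amplitude smooth noise field for hematoxylin background texture."""
    if amplitude <= 0:
        return np.zeros(shape)
    raw = rng.normal(0.0, 1.0, shape)
    sm = ndimage.gaussian_filter(raw, sigma_px)
    sd = sm.std()
    return sm / sd * amplitude if sd > 0 else np.zeros(shape)


def conc_to_rgb(hema: np.ndarray, dab: np.ndarray,
                vectors: StainVectors | None = None,
                background_i0: float = 255.0, quantize: bool = True) -> np.ndarray:
    """Beer-Lambert forward model: concentrations -> RGB transmitted light."""
    vectors = vectors or default_hdab_vectors()
    conc = np.stack([hema, dab, np.zeros_like(hema)], axis=-1)
    if np.any(conc < 0):
        raise ValueError("negative stain amounts")
    od = conc @ vectors.matrix.T
    return od_to_rgb(od, background_i0, quantize=quantize)


def render_slide(cells, vessels, shape, stain_kind: str, pixel_size_um: float,
                 background_i0: float = 255.0, seed: int | None = 0,
                 rng: np.random.Generator | None = None,
                 hema_background: float = 0.30, texture: np.ndarray | None = None,
                 noise_sd: float = 0.0, vectors: StainVectors | None = None,
                 subject_id: str = "") -> StainImage:
    """Render one brightfield slide from object specifications.

    The RGB pixel is ``I0 * 10**(-M @ c)`` channel-wise, where the
    concentration vector ``c`` accumulates per-object DAB amounts, the
    hematoxylin background (plus optional smooth texture) and additive
    Gaussian noise.  Deterministic for a fixed seed.
    """
    rng = rng or np.random.default_rng(seed)
    draw_cells = [] if stain_kind == "HE" else list(cells)
    maps = build_concentration_maps(draw_cells, vessels, shape, pixel_size_um,
                                    hema_background=hema_background,
                                    texture=texture, noise_sd=noise_sd, rng=rng)
    rgb = conc_to_rgb(maps["hematoxylin"], maps["dab"], vectors, background_i0)
    return StainImage(pixels=rgb, pixel_size_um=pixel_size_um,
                      stain_kind=stain_kind, subject_id=subject_id)


# ---------------------------------------------------------------------------
# object placement
# ---------------------------------------------------------------------------

def scatter_cells(n: int, roi_mask: np.ndarray, rng: np.random.Generator,
                  make_cell, min_spacing_px: float, max_tries: int = 200):
    """Place ``n`` cells uniformly in a mask with a minimum centre spacing.

    ``make_cell(x, y)`` builds the CellSpec for an accepted centre.  Raises
    when the region cannot hold the requested count at the given spacing.
    """
    ys, xs = np.nonzero(np.asarray(roi_mask, bool))
    if len(ys) == 0 and n > 0:
        raise ValueError("cannot place cells in an empty mask")
    placed = []
    centres = []
    sq = min_spacing_px ** 2
    for _ in range(n):
        for attempt in range(max_tries):
            i = int(rng.integers(len(ys)))
            x, y = float(xs[i]), float(ys[i])
            if all((x - px) ** 2 + (y - py) ** 2 >= sq for px, py in centres):
                centres.append((x, y))
                placed.append(make_cell(x, y))
                break
        else:
            raise ValueError(
                f"could not place {n} cells at spacing {min_spacing_px:.1f} px; "
                "reduce the target density")
    return placed


def _annulus_geometry(vessel: VesselSpec, shape, pixel_size_um: float,
                      distance_um: float = 15.0):
    lumen = vessel_lumen_mask(vessel, shape, pixel_size_um)
    dist = ndimage.distance_transform_edt(~lumen) * pixel_size_um
    annulus = (dist > 0) & (dist <= distance_um)
    area_mm2 = float(annulus.sum()) * (pixel_size_um / 1000.0) ** 2
    return lumen, dist, annulus, area_mm2


def make_vessel_with_density(vessel: VesselSpec, target_density: float,
                             shape, pixel_size_um: float,
                             rng: np.random.Generator,
                             soma_radius_um: float = 3.0, n_branches: int = 5,
                             branch_length_um: float = 5.0,
                             stain_amount: float = 0.8,
                             distance_um: float = 15.0):
    """Populate a vessel's 15 µm annulus with astroglia at a target density.

    Places ``round(target_density * annulus_area_mm2)`` star-shaped astroglia
    uniformly in the annulus with a minimum centre spacing of twice the soma
    radius, so the realised density is within one count of the target.
    Returns ``(cells, annulus_area_mm2, min_distance_um)`` where the last
    value is the smallest placed-soma distance to the lumen (inf if empty).
    """
    if target_density < 0:
        raise ValueError("target density must be nonnegative")
    _, dist, annulus, area_mm2 = _annulus_geometry(vessel, shape, pixel_size_um,
                                                   distance_um)
    n = int(round(target_density * area_mm2))
    # one extra pixel so neighbouring somata never share an 8-neighbourhood
    spacing_px = 2.0 * soma_radius_um / pixel_size_um + 1.0
    # keep the soma clear of the lumen: the whole cell body stays in tissue
    placement = annulus & (dist >= soma_radius_um)
    if n > 0 and not placement.any():
        raise ValueError("annulus too narrow for the requested soma radius")

    def make(x, y):
        return CellSpec(center_xy=(x, y), phenotype="astro_star",
                        soma_radius_um=soma_radius_um, n_branches=n_branches,
                        branch_length_um=branch_length_um,
                        stain_amount=stain_amount,
                        orientation_rad=float(rng.uniform(0, 2 * math.pi)),
                        branch_width_px=1)

    cells = scatter_cells(n, placement, rng, make, spacing_px)
    if cells:
        min_dist = min(dist[int(round(c.center_xy[1])), int(round(c.center_xy[0]))]
                       for c in cells)
    else:
        min_dist = float("inf")
    return cells, area_mm2, float(min_dist)


# ---------------------------------------------------------------------------
# MRI counterpart
# ---------------------------------------------------------------------------

class SinusoidalWarp:
    """Affine plus a smooth low-amplitude sinusoidal displacement field."""

    kind = "warp"

    def __init__(self, affine: Transform2D, amplitude_px: float,
                 wavelength_px: float = 200.0):
        self.affine = affine
        self.amplitude_px = amplitude_px
        self.wavelength_px = wavelength_px

    def apply(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        out = self.affine.apply(pts)
        w = 2 * math.pi / self.wavelength_px
        out = out + self.amplitude_px * np.column_stack(
            [np.sin(w * pts[:, 1]), np.cos(w * pts[:, 0])])
        return out


def make_mri_counterpart(histology_gray: np.ndarray, pixel_size_um: float,
                         rotation_deg: float = 5.0, scale: float = 1.0,
                         translation_px=(0.0, 0.0), downsample_factor: int = 8,
                         blur_px: float = 1.5, warp_amplitude_px: float = 0.0,
                         n_landmarks: int = 12,
                         rng: np.random.Generator | None = None):
    """Degraded MRI-like counterpart of a histology frame with known truth.

    The truth transform maps MRI pixel coordinates to histology pixel
    coordinates: a rotation/scale/translation affine (scale includes the
    downsampling factor) with an optional smooth warp.  The MRI image is
    the histology intensity sampled through the truth map, blurred,
    and monotonically intensity-remapped.  Returns
    ``(mri_image_uint8, truth_transform, (landmarks_moving, landmarks_fixed))``
    with at least 10 exactly corresponding landmark pairs.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    rng = rng or np.random.default_rng(0)
    hist = np.asarray(histology_gray, float)
    h, w = hist.shape
    s = scale * downsample_factor
    th = math.radians(rotation_deg)
    a, b = s * math.cos(th), -s * math.sin(th)
    c, d = s * math.sin(th), s * math.cos(th)
    if abs(a * d - b * c) < 1e-9:
        raise ValueError("degenerate affine (determinant ~ 0)")
    # centre the histology frame in the MRI frame
    mh = int(math.ceil(h / downsample_factor * 1.3))
    mw = int(math.ceil(w / downsample_factor * 1.3))
    centre_m = np.array([mw / 2.0, mh / 2.0])
    centre_h = np.array([w / 2.0, h / 2.0])
    t = centre_h - np.array([a * centre_m[0] + b * centre_m[1],
                             c * centre_m[0] + d * centre_m[1]])
    t += np.asarray(translation_px, float)
    affine = Transform2D.from_affine_params(a, b, t[0], c, d, t[1])
    truth = affine if warp_amplitude_px == 0 else SinusoidalWarp(affine, warp_amplitude_px)

    ys, xs = np.mgrid[0:mh, 0:mw]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = truth.apply(pts)
    coords = np.stack([src[:, 1].reshape(mh, mw), src[:, 0].reshape(mh, mw)])
    mri = ndimage.map_coordinates(hist, coords, order=1, mode="constant", cval=0.0)
    if blur_px > 0:
        mri = ndimage.gaussian_filter(mri, blur_px)
    # monotone (decreasing) intensity remap: bright histology -> dark MRI-like
    mri = 235.0 - 0.8 * mri
    mri = np.clip(np.round(mri), 0, 255).astype(np.uint8)

    # landmarks on a lattice over the MRI frame, exact under the truth map
    n_side = max(2, int(math.ceil(math.sqrt(n_landmarks))))
    gx = np.linspace(0.15 * mw, 0.85 * mw, n_side)
    gy = np.linspace(0.15 * mh, 0.85 * mh, n_side)
    lattice = np.array([(x, y) for y in gy for x in gx])[:max(n_landmarks, 10)]
    moving = lattice
    fixed = truth.apply(moving)
    return mri, truth, (moving, fixed)


def warp_mask_to_mri(mask: np.ndarray, truth, mri_shape) -> np.ndarray:
    """Carry a histology-grid binary mask onto the MRI grid via the truth map."""
    mh, mw = mri_shape
    ys, xs = np.mgrid[0:mh, 0:mw]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = truth.apply(pts)
    coords = np.stack([src[:, 1].reshape(mh, mw), src[:, 0].reshape(mh, mw)])
    out = ndimage.map_coordinates(np.asarray(mask, float), coords, order=0,
                                  mode="constant", cval=0.0)
    return out > 0.5


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_roi_masks(shape) -> dict:
    """Two disjoint rectangular ROIs: NAWM (top band) and WMH (bottom band)."""
    h, w = shape
    nawm = np.zeros(shape, bool)
    wmh = np.zeros(shape, bool)
    nawm[int(0.09 * h):int(0.44 * h), int(0.09 * w):int(0.91 * w)] = True
    wmh[int(0.56 * h):int(0.91 * h), int(0.09 * w):int(0.91 * w)] = True
    return {"NAWM": nawm, "WMH": wmh}


def outcome_value(eff: dict, is_htn: bool, is_wmh: bool, age: float,
                  fixation: float, fazekas: int, noise: float) -> float:
    """Linear outcome model: baseline + group + ROI + covariates + noise."""
    value = (eff["baseline"]
             + eff["group_delta"] * float(is_htn)
             + eff["roi_delta"] * float(is_wmh)
             + eff["age_coef"] * (age - 80.0)
             + eff["fix_coef"] * (fixation - 11.0)
             + eff["burden_delta"] * float(fazekas >= 2)
             + noise)
    return value


def draw_subject_record(i: int, group: str, rng: np.random.Generator) -> SubjectRecord:
    age = float(np.clip(rng.normal(80.0, 8.0), 55.0, 100.0))
    sex = "F" if rng.random() < 0.5 else "M"
    fixation = float(np.clip(rng.normal(11.0, 6.0), 1.0, 40.0))
    if group == "control":
        fazekas = int(rng.choice([0, 1], p=[0.3, 0.7]))
    else:
        fazekas = int(rng.choice([0, 1, 2, 3], p=[0.10, 0.30, 0.50, 0.10]))
    extra = {"bmi": float(np.clip(rng.normal(23.0, 4.0), 15.0, 40.0)),
             "diabetes": int(rng.random() < 0.2),
             "hypercholesterolemia": int(rng.random() < 0.5),
             "smoking": int(rng.random() < 0.3),
             "alcohol": int(rng.random() < 0.15)}
    return SubjectRecord(subject_id=f"S{i:02d}", group=group, age=age, sex=sex,
                         fixation_interval_months=fixation, fazekas=fazekas,
                         extra=extra)


def sample_outcome_table(spec: CohortSpec, rng: np.random.Generator,
                         subjects=None) -> pd.DataFrame:
    """Draw true outcome values for every (subject, ROI) without rendering.

    Long-format frame with covariates, used both to parameterise object
    placement and directly for statistical calibration studies.
    """
    if subjects is None:
        groups = ["hypertension"] * spec.n_hypertension + ["control"] * spec.n_control
        subjects = [draw_subject_record(i, g, rng) for i, g in enumerate(groups)]
    rows = []
    for rec in subjects:
        for roi in ("NAWM", "WMH"):
            row = {"subject_id": rec.subject_id, "group": rec.group,
                   "roi_name": roi, "age": rec.age, "sex": rec.sex,
                   "fixation_interval_months": rec.fixation_interval_months,
                   "fazekas": rec.fazekas}
            for name, eff in spec.effects.items():
                noise = rng.normal(0.0, eff["sd"]) if eff["sd"] > 0 else 0.0
                row[name] = outcome_value(eff, rec.group == "hypertension",
                                          roi == "WMH", rec.age,
                                          rec.fixation_interval_months,
                                          rec.fazekas, noise)
            rows.append(row)
    return pd.DataFrame(rows)


def _microglia_for_roi(row, roi_mask, spec: CohortSpec, rng,
                       exclude_mask=None) -> list:
    area = mask_area_mm2(roi_mask, spec.pixel_size_um)
    n = max(0, int(round(max(row["iba1_frequency_per_mm2"], 0.0) * area)))
    amoeboid_frac = float(np.clip(row["iba1_amoeboid_fraction"], 0.0, 1.0))
    base_od = max(row["iba1_stain_od"], 0.1)
    base_len = max(row["iba1_branch_length_um"], 5.0)
    soma_px = spec.microglia_soma_um / spec.pixel_size_um
    spacing = 2 * soma_px + base_len / spec.pixel_size_um
    # keep branches inside the frame
    margin = int(math.ceil(soma_px + (base_len + 8) / spec.pixel_size_um))
    inner = np.zeros_like(roi_mask)
    inner[margin:-margin, margin:-margin] = True
    placeable = roi_mask & inner
    if exclude_mask is not None:
        placeable &= ~exclude_mask

    def make(x, y):
        amoeboid = rng.random() < amoeboid_frac
        length = 0.0 if amoeboid else float(np.clip(rng.normal(base_len, 2.0),
                                                    5.0, base_len + 8.0))
        return CellSpec(center_xy=(x, y),
                        phenotype="amoeboid" if amoeboid else "ramified",
                        soma_radius_um=spec.microglia_soma_um,
                        n_branches=0 if amoeboid else spec.microglia_branches,
                        branch_length_um=length,
                        stain_amount=float(np.clip(rng.normal(base_od, 0.05),
                                                   0.1, 2.0)),
                        orientation_rad=float(rng.uniform(0, 2 * math.pi)))

    return scatter_cells(n, placeable, rng, make, spacing)


def _astroglia_for_roi(row, roi_mask, spec: CohortSpec, rng,
                       exclude_mask=None) -> list:
    area = mask_area_mm2(roi_mask, spec.pixel_size_um)
    n = max(0, int(round(max(row["gfap_density_per_mm2"], 0.0) * area)))
    base_od = max(row["gfap_stain_od"], 0.1)
    soma_px = spec.astro_soma_um / spec.pixel_size_um
    spacing = 2 * soma_px + spec.astro_branch_um / spec.pixel_size_um
    margin = int(math.ceil(soma_px + (spec.astro_branch_um + 4) / spec.pixel_size_um))
    inner = np.zeros_like(roi_mask)
    inner[margin:-margin, margin:-margin] = True
    placeable = roi_mask & inner
    if exclude_mask is not None:
        placeable &= ~exclude_mask

    def make(x, y):
        return CellSpec(center_xy=(x, y), phenotype="astro_star",
                        soma_radius_um=spec.astro_soma_um,
                        n_branches=spec.astro_branches,
                        branch_length_um=spec.astro_branch_um,
                        stain_amount=float(np.clip(rng.normal(base_od, 0.05),
                                                   0.1, 2.0)),
                        orientation_rad=float(rng.uniform(0, 2 * math.pi)),
                        branch_width_px=1)

    return scatter_cells(n, placeable, rng, make, spacing)


def _vessels_for_roi(row, roi_mask, spec: CohortSpec, rng) -> list:
    ys, xs = np.nonzero(roi_mask)
    r0, r1 = ys.min(), ys.max()
    c0, c1 = xs.min(), xs.max()
    vessels = []
    tries = 0
    while len(vessels) < spec.vessels_per_roi and tries < 500:
        tries += 1
        a = float(rng.uniform(*spec.lumen_radius_range_um))
        b = float(a * rng.uniform(0.6, 1.0))
        margin = (a + 25.0) / spec.pixel_size_um
        if r1 - r0 < 2 * margin or c1 - c0 < 2 * margin:
            break
        y = float(rng.uniform(r0 + margin, r1 - margin))
        x = float(rng.uniform(c0 + margin, c1 - margin))
        too_close = any(
            math.hypot(x - v.center_xy[0], y - v.center_xy[1]) * spec.pixel_size_um
            < (a + max(v.lumen_axes_um) + 45.0) for v in vessels)
        if too_close:
            continue
        density = max(0.0, float(rng.normal(row["peri_density_per_mm2"], 60.0)))
        scar = bool(rng.random() < np.clip(row["scar_probability"], 0.0, 1.0))
        vessels.append(VesselSpec(center_xy=(x, y), lumen_axes_um=(a, b),
                                  orientation_rad=float(rng.uniform(0, math.pi)),
                                  perivascular_density_per_mm2=density,
                                  scar=scar))
    return vessels


def _true_microglia_metrics(cells) -> dict:
    n = len(cells)
    amoeboid = sum(1 for c in cells if c.phenotype == "amoeboid")
    lengths = [c.branch_length_um for c in cells if c.phenotype == "ramified"]
    return {
        "n_cells": n,
        "amoeboid_fraction": amoeboid / n if n else float("nan"),
        "mean_branch_length_um": float(np.mean(lengths)) if lengths else 0.0,
        "mean_stain_od": float(np.mean([c.stain_amount for c in cells])) if n else 0.0,
    }


def generate_subject(rec: SubjectRecord, row_by_roi: dict, spec: CohortSpec,
                     rng: np.random.Generator) -> dict:
    """Build all in-memory data for one subject; returns a truth dictionary."""
    shape = spec.slide_shape
    px = spec.pixel_size_um
    rois = default_roi_masks(shape)

    microglia, astroglia, vessels = [], [], []
    vessel_truth = []
    roi_truth = {}
    for roi_name, roi_mask in rois.items():
        row = row_by_roi[roi_name]
        v_specs = _vessels_for_roi(row, roi_mask, spec, rng)
        # parenchymal cells stay clear of the perivascular zones, so the
        # annulus density is controlled by the per-vessel targets alone
        exclude = np.zeros(shape, bool)
        for v in v_specs:
            lumen = vessel_lumen_mask(v, shape, px)
            dist = ndimage.distance_transform_edt(~lumen) * px
            exclude |= dist <= 25.0
        m_cells = _microglia_for_roi(row, roi_mask, spec, rng, exclude)
        a_cells = _astroglia_for_roi(row, roi_mask, spec, rng, exclude)
        peri_cells_all = []
        for v in v_specs:
            p_cells, area_mm2, min_dist = make_vessel_with_density(
                v, v.perivascular_density_per_mm2, shape, px, rng,
                soma_radius_um=spec.astro_soma_um,
                n_branches=spec.astro_branches,
                branch_length_um=spec.astro_branch_um)
            count = len(p_cells)
            density = count / area_mm2
            vessel_truth.append({
                "roi_name": roi_name,
                "center_xy": list(v.center_xy),
                "lumen_axes_um": list(v.lumen_axes_um),
                "scar": v.scar,
                "annulus_area_mm2": area_mm2,
                "astro_count": count,
                "density_per_mm2": density,
                "grade": grade_vessel(density, count, v.scar),
                "close_range": bool(min_dist <= 5.0),
            })
            peri_cells_all.extend(p_cells)
        microglia.extend((roi_name, c) for c in m_cells)
        astroglia.extend((roi_name, c) for c in a_cells + peri_cells_all)
        vessels.extend(v_specs)
        roi_truth[roi_name] = {
            "microglia": _true_microglia_metrics(m_cells),
            "n_astroglia": len(a_cells) + len(peri_cells_all),
            "gfap_mean_stain_od": float(np.mean([c.stain_amount for c in a_cells]))
            if a_cells else 0.0,
            "outcome_row": {k: float(v) for k, v in row.items()
                            if isinstance(v, (int, float, np.floating))},
        }

    texture = smooth_texture(shape, spec.texture_amp, rng)
    shift = rng.uniform(-spec.stain_shift_px, spec.stain_shift_px, size=(2, 2))

    def shifted(cells, vessels_, dxy):
        dx, dy = dxy
        cs = [dataclasses.replace(c, center_xy=(c.center_xy[0] + dx,
                                                c.center_xy[1] + dy))
              for c in cells]
        vs = [dataclasses.replace(v, center_xy=(v.center_xy[0] + dx,
                                                v.center_xy[1] + dy))
              for v in vessels_]
        return cs, vs

    he = render_slide([], vessels, shape, "HE", px, spec.background_i0,
                      rng=rng, hema_background=spec.hema_background,
                      texture=texture, noise_sd=spec.noise_sd,
                      subject_id=rec.subject_id)
    iba1_cells, iba1_vessels = shifted([c for _, c in microglia], vessels, shift[0])
    gfap_cells, gfap_vessels = shifted([c for _, c in astroglia], vessels, shift[1])
    iba1 = render_slide(iba1_cells, iba1_vessels, shape, "IBA1_DAB", px,
                        spec.background_i0, rng=rng,
                        hema_background=spec.hema_background,
                        texture=np.roll(texture, (int(round(shift[0][1])),
                                                  int(round(shift[0][0]))), (0, 1)),
                        noise_sd=spec.noise_sd, subject_id=rec.subject_id)
    gfap = render_slide(gfap_cells, gfap_vessels, shape, "GFAP_DAB", px,
                        spec.background_i0, rng=rng,
                        hema_background=spec.hema_background,
                        texture=np.roll(texture, (int(round(shift[1][1])),
                                                  int(round(shift[1][0]))), (0, 1)),
                        noise_sd=spec.noise_sd, subject_id=rec.subject_id)

    he_gray = he.pixels.mean(axis=2)
    rotation = float(rng.uniform(*spec.mri_rotation_deg_range))
    scale = float(rng.uniform(*spec.mri_scale_range))
    mri, truth_transform, (lm_moving, lm_fixed) = make_mri_counterpart(
        he_gray, px, rotation_deg=rotation, scale=scale,
        downsample_factor=spec.mri_downsample, blur_px=spec.mri_blur_px,
        n_landmarks=spec.n_landmarks, rng=rng)
    mri_rois = {name: warp_mask_to_mri(mask, truth_transform, mri.shape)
                for name, mask in rois.items()}

    return {
        "record": rec,
        "slides": {"HE": he, "IBA1_DAB": iba1, "GFAP_DAB": gfap},
        "roi_masks_hist": rois,
        "roi_masks_mri": mri_rois,
        "mri": mri,
        "truth_transform": truth_transform,
        "landmarks": (lm_moving, lm_fixed),
        "stain_shift_px": shift,
        "cells": {"microglia": microglia, "astroglia": astroglia},
        "vessels": vessels,
        "vessel_truth": vessel_truth,
        "roi_truth": roi_truth,
    }


def _truth_json(subject: dict) -> dict:
    rec = subject["record"]
    lm_m, lm_f = subject["landmarks"]
    tt = subject["truth_transform"]
    return {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "roi_truth": subject["roi_truth"],
        "vessel_truth": subject["vessel_truth"],
        "stain_shift_px": np.asarray(subject["stain_shift_px"]).tolist(),
        "truth_transform": json.loads(tt.to_json()) if isinstance(tt, Transform2D)
        else {"kind": "warp"},
        "landmarks_moving": lm_m.tolist(),
        "landmarks_fixed": lm_f.tolist(),
        "cells": {
            kind: [{"roi": roi, **dataclasses.asdict(c)} for roi, c in cells]
            for kind, cells in subject["cells"].items()
        },
        "vessels": [dataclasses.asdict(v) for v in subject["vessels"]],
    }


def generate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Generate the full synthetic cohort on disk.

    Writes, per subject, the three stained slides, MRI counterpart, ROI
    masks on both grids, landmark pairs and a ground-truth JSON, plus the
    cohort metadata table.  Deterministic (including file bytes) for a
    fixed ``CohortSpec``.  Returns ``{"subjects": [...], "table": DataFrame,
    "out_dir": Path}`` with the in-memory truth retained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = ["hypertension"] * spec.n_hypertension + ["control"] * spec.n_control
    records = [draw_subject_record(i, g, np.random.default_rng([spec.seed, 1000 + i]))
               for i, g in enumerate(groups)]
    outcome_rng = np.random.default_rng([spec.seed, 7])
    table = sample_outcome_table(spec, outcome_rng, subjects=records)

    subjects = []
    for i, rec in enumerate(records):
        rng = np.random.default_rng([spec.seed, i])
        rows = {roi: table[(table.subject_id == rec.subject_id)
                           & (table.roi_name == roi)].iloc[0]
                for roi in ("NAWM", "WMH")}
        subject = generate_subject(rec, rows, spec, rng)
        subjects.append(subject)
        sdir = out_dir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        write_stain_image(subject["slides"]["HE"], sdir / "he.tiff")
        write_stain_image(subject["slides"]["IBA1_DAB"], sdir / "iba1.tiff")
        write_stain_image(subject["slides"]["GFAP_DAB"], sdir / "gfap.tiff")
        iio.imwrite(sdir / "mri.png", subject["mri"])
        for name, mask in subject["roi_masks_mri"].items():
            write_mask(mask, sdir / f"mri_{name}.png")
        for name, mask in subject["roi_masks_hist"].items():
            write_mask(mask, sdir / f"truth_{name}.png")
        lm_m, lm_f = subject["landmarks"]
        write_landmarks(lm_m, lm_f, sdir / "landmarks.csv")
        (sdir / "truth.json").write_text(json.dumps(_truth_json(subject), indent=1))

    df = cohort_to_dataframe(records)
    df.to_csv(out_dir / "cohort.csv", index=False)
    table.to_csv(out_dir / "true_outcomes.csv", index=False)
    return {"subjects": subjects, "records": records, "table": table,
            "out_dir": out_dir}
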
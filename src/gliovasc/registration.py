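"""Planar registration: landmark (affine / thin-plate spline) and intensity.

Two registration problems are solved here:

* transferring ROIs drawn on a 2D MRI slice onto the reference HE section,
  via paired landmarks (affine least squares by default, exact thin-plate
  spline interpolation optionally);
* co-registering adjacent stained sections (IBA1 / GFAP) to the HE
  reference, via multi-resolution affine optimisation of a multimodal
  similarity (Mattes mutual information by default), with landmark
  registration as the manual fallback when the automated step fails.

A ``Transform2D`` maps *moving* points to *fixed* points in (x, y) pixel
coordinates; image warping resamples by inverse mapping, so masks stay
strictly binary (nearest-neighbour) and images are interpolated bilinearly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from .imaging_io import RoiSet

logger = logging.getLogger(__name__)

#: operating standard for landmark counts; fewer only warns
RECOMMENDED_MIN_LANDMARKS = 10

#: allowed MI loss relative to the initial transform before flagging failure
MI_GAIN_TOLERANCE_NATS = 0.05
#: minimum absolute mutual information for a believable registration
MI_FLOOR_NATS = 0.10


@dataclass(frozen=True)
class LandmarkSet:
    """Paired (moving, fixed) points in pixel units."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.moving, float)
        f = np.asarray(self.fixed, float)
        if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 2:
            raise ValueError("landmarks must be matched (n, 2) arrays")
        if len(m) < 3:
            raise ValueError("at least 3 landmark pairs are required")
        object.__setattr__(self, "moving", m)
        object.__setattr__(self, "fixed", f)

    @property
    def n(self) -> int:
        return len(self.moving)


class Transform2D:
    """Invertible planar mapping between two pixel grids.

    ``kind`` is ``"affine"`` (3x3 homogeneous matrix) or ``"tps"``
    (thin-plate spline interpolant; the inverse is the spline fitted on the
    swapped point pairs, exact at the landmarks for smoothing 0).
    """

    def __init__(self, kind: str, matrix: np.ndarray | None = None,
                 control_moving: np.ndarray | None = None,
                 control_fixed: np.ndarray | None = None,
                 smoothing: float = 0.0):
        if kind not in ("affine", "tps"):
            raise ValueError("kind must be 'affine' or 'tps'")
        self.kind = kind
        self.smoothing = float(smoothing)
        if kind == "affine":
            m = np.asarray(matrix, float)
            if m.shape != (3, 3):
                raise ValueError("affine matrix must be 3x3")
            det = np.linalg.det(m[:2, :2])
            if abs(det) < 1e-12:
                raise ValueError("degenerate affine (determinant ~ 0)")
            self.matrix = m
            self._fwd = None
            self._inv = None
        else:
            cm = np.asarray(control_moving, float)
            cf = np.asarray(control_fixed, float)
            self.control_moving = cm
            self.control_fixed = cf
            self._fwd = RBFInterpolator(cm, cf, kernel="thin_plate_spline",
                                        smoothing=self.smoothing, degree=1)
            self._inv = RBFInterpolator(cf, cm, kernel="thin_plate_spline",
                                        smoothing=self.smoothing, degree=1)
            self.matrix = None

    # -- construction -----------------------------------------------------
    @classmethod
    def identity(cls) -> "Transform2D":
        return cls("affine", matrix=np.eye(3))

    @classmethod
    def from_affine_params(cls, a, b, tx, c, d, ty) -> "Transform2D":
        """x' = a x + b y + tx ;  y' = c x + d y + ty."""
        return cls("affine", matrix=np.array([[a, b, tx], [c, d, ty], [0, 0, 1.0]]))

    # -- mapping ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "affine":
            homo = np.column_stack([pts, np.ones(len(pts))])
            return (homo @ self.matrix.T)[:, :2]
        return self._fwd(pts)

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "affine":
            inv = np.linalg.inv(self.matrix)
            homo = np.column_stack([pts, np.ones(len(pts))])
            return (homo @ inv.T)[:, :2]
        return self._inv(pts)

    def inverse(self) -> "Transform2D":
        if self.kind == "affine":
            return Transform2D("affine", matrix=np.linalg.inv(self.matrix))
        return Transform2D("tps", control_moving=self.control_fixed,
                           control_fixed=self.control_moving,
                           smoothing=self.smoothing)

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        if self.kind == "affine":
            payload = {"kind": "affine", "matrix": self.matrix.tolist()}
        else:
            payload = {
                "kind": "tps",
                "control_moving": self.control_moving.tolist(),
                "control_fixed": self.control_fixed.tolist(),
                "smoothing": self.smoothing,
            }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Transform2D":
        payload = json.loads(text)
        if payload["kind"] == "affine":
            return cls("affine", matrix=np.array(payload["matrix"]))
        return cls("tps",
                   control_moving=np.array(payload["control_moving"]),
                   control_fixed=np.array(payload["control_fixed"]),
                   smoothing=payload.get("smoothing", 0.0))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "Transform2D":
        return cls.from_json(Path(path).read_text())


@dataclass
class RegistrationResult:
    transform: Transform2D
    rmse_px: float  # landmark residual, or final similarity for intensity mode
    method: str  # "landmark" | "intensity" | "manual_fallback"
    converged: bool = True
    n_landmarks: int | None = None


def fit_landmark_transform(landmarks: LandmarkSet, kind: str = "affine",
                           method_tag: str = "landmark") -> RegistrationResult:
    """Fit an affine (least squares) or TPS (exact interpolant) to landmarks.

    Warns, but proceeds, below the operating standard of 10 pairs.
    """
    if landmarks.n < RECOMMENDED_MIN_LANDMARKS:
        logger.warning("only %d landmark pairs (operating standard is >= %d)",
                       landmarks.n, RECOMMENDED_MIN_LANDMARKS)
    moving, fixed = landmarks.moving, landmarks.fixed
    if kind == "affine":
        centered = moving - moving.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max())) < 2:
            raise ValueError("landmarks are collinear; affine fit is degenerate")
        design = np.column_stack([moving, np.ones(landmarks.n)])
        coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
        matrix = np.eye(3)
        matrix[0, :] = coef[:, 0]  # a, b, tx acting on (x, y, 1)
        matrix[1, :] = coef[:, 1]
        transform = Transform2D("affine", matrix=matrix)
    elif kind == "tps":
        uniq = np.unique(fixed, axis=0)
        if len(uniq) != len(fixed):
            raise ValueError("duplicate fixed points; TPS system is singular")
        if len(np.unique(moving, axis=0)) != len(moving):
            raise ValueError("duplicate moving points; TPS system is singular")
        transform = Transform2D("tps", control_moving=moving, control_fixed=fixed)
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    residual = transform.apply(moving) - fixed
    rmse = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    return RegistrationResult(transform=transform, rmse_px=rmse,
                              method=method_tag, converged=True,
                              n_landmarks=landmarks.n)


def warp_image(image: np.ndarray, transform: Transform2D, output_shape,
               interpolation: str = "linear", background: float = 0.0) -> np.ndarray:
    """Resample ``image`` (on the moving grid) onto the fixed grid.

    Inverse mapping: each output pixel samples the moving image at
    ``T^-1(pixel)``.  ``interpolation`` is ``"linear"`` for images or
    ``"nearest"`` for masks; nearest-neighbour output of a boolean input is
    strictly binary.
    """
    arr = np.asarray(image)
    was_bool = arr.dtype == bool
    order = 0 if interpolation == "nearest" else 1
    h, w = output_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = transform.apply_inverse(pts)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])

    def _resample(channel):
        return ndimage.map_coordinates(channel.astype(float), coords, order=order,
                                       mode="constant", cval=background)

    if arr.ndim == 3:
        out = np.stack([_resample(arr[:, :, c]) for c in range(arr.shape[2])], axis=2)
    else:
        out = _resample(arr)
    if was_bool:
        return out > 0.5
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.round(out), info.min, info.max).astype(arr.dtype)
    return out


# ---------------------------------------------------------------------------
# intensity-based multimodal registration (stained section -> HE reference)
# ---------------------------------------------------------------------------

def _sitk_affine_to_transform(tx: sitk.Transform) -> Transform2D:
    """Convert a SimpleITK (fixed->moving) affine into our moving->fixed map."""
    tx = tx.Downcast() if not isinstance(tx, sitk.AffineTransform) else tx
    if isinstance(tx, sitk.CompositeTransform):
        if tx.GetNumberOfTransforms() != 1:
            raise ValueError("unexpected composite transform from registration")
        tx = tx.GetNthTransform(0).Downcast()
    tx = sitk.AffineTransform(tx)
    a = np.array(tx.GetMatrix()).reshape(2, 2)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    # p_moving = A (p_fixed - c) + c + t
    matrix = np.eye(3)
    matrix[:2, :2] = a
    matrix[:2, 2] = -a @ c + c + t
    fixed_to_moving = Transform2D("affine", matrix=matrix)
    return fixed_to_moving.inverse()


def _transform_to_sitk_affine(transform: Transform2D) -> sitk.AffineTransform:
    """Our moving->fixed affine, as a SimpleITK fixed->moving transform."""
    inv = np.linalg.inv(transform.matrix)
    tx = sitk.AffineTransform(2)
    tx.SetMatrix(inv[:2, :2].ravel().tolist())
    tx.SetTranslation(inv[:2, 2].tolist())
    return tx


def _make_registration(metric: str, sampling: float | None) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    if metric == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    elif metric == "ncc":
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    if sampling is None:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    return reg


def register_intensity(moving: np.ndarray, fixed: np.ndarray,
                       init_transform: Transform2D | None = None,
                       metric: str = "mi",
                       shrink_factors=(4, 2, 1),
                       smoothing_sigmas=(2.0, 1.0, 0.0),
                       sampling: float | None = 0.25,
                       iterations: int = 150) -> RegistrationResult:
    """Affine intensity registration of two single-channel rasters.

    Multi-resolution (three pyramid levels) optimisation of Mattes mutual
    information (or normalised correlation with ``metric="ncc"``).  Intended
    inputs are hematoxylin concentration maps of adjacent sections.

    The result is flagged ``converged=False`` — signalling the manual
    landmark fallback — when either image is degenerate (near-constant),
    the similarity is non-finite, the mutual information lost more than
    0.05 nats relative to the initial transform, or the final mutual
    information stays below an absolute floor of 0.1 nats.
    """
    mov = np.asarray(moving, float)
    fix = np.asarray(fixed, float)
    if mov.ndim != 2 or fix.ndim != 2:
        raise ValueError("intensity registration expects single-channel images")
    init = init_transform or Transform2D.identity()
    if mov.std() < 1e-9 or fix.std() < 1e-9:
        logger.warning("degenerate (near-constant) image; intensity registration skipped")
        return RegistrationResult(transform=init, rmse_px=float("nan"),
                                  method="intensity", converged=False)

    fixed_img = sitk.GetImageFromArray(fix.astype(np.float32))
    moving_img = sitk.GetImageFromArray(mov.astype(np.float32))
    if init_transform is None:
        # moments initialisation absorbs gross translation before optimisation
        init_sitk = sitk.CenteredTransformInitializer(
            fixed_img, moving_img, sitk.AffineTransform(2),
            sitk.CenteredTransformInitializerFilter.MOMENTS)
        init = _sitk_affine_to_transform(init_sitk)

    # similarity at the initial transform, for the convergence policy
    probe = _make_registration(metric, sampling)
    try:
        init_metric = probe.MetricEvaluate(
            fixed_img, moving_img) if _set_initial(probe, init) else float("nan")
    except RuntimeError:
        init_metric = float("nan")

    reg = _make_registration(metric, sampling)
    _set_initial(reg, init)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    try:
        final_sitk = reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:
        logger.warning("intensity registration failed: %s", exc)
        return RegistrationResult(transform=init, rmse_px=float("nan"),
                                  method="intensity", converged=False)

    transform = _sitk_affine_to_transform(final_sitk)
    # re-evaluate the final similarity under the same probe conditions as
    # the initial one, so the convergence comparison is apples to apples
    probe2 = _make_registration(metric, sampling)
    try:
        _set_initial(probe2, transform)
        final_metric = probe2.MetricEvaluate(fixed_img, moving_img)
    except RuntimeError:
        final_metric = float("nan")
    # the optimiser can end a sub-pixel step past the best-scoring pose;
    # keep whichever of {initial, final} scores better
    if np.isfinite(init_metric) and (not np.isfinite(final_metric)
                                     or init_metric < final_metric):
        transform = init
        final_metric = init_metric
    converged = np.isfinite(final_metric)
    if metric == "mi":
        # Mattes metric is negative MI (nats): smaller is better.
        mi_final = -final_metric
        mi_init = -init_metric if np.isfinite(init_metric) else 0.0
        if mi_final < mi_init - MI_GAIN_TOLERANCE_NATS:
            converged = False
        if mi_final < MI_FLOOR_NATS:
            converged = False
    if not converged:
        logger.warning("intensity registration did not converge "
                       "(similarity %.4f, initial %.4f)", final_metric, init_metric)
    return RegistrationResult(transform=transform, rmse_px=float(final_metric),
                              method="intensity", converged=converged)


def _set_initial(reg: sitk.ImageRegistrationMethod, init: Transform2D) -> bool:
    reg.SetInitialTransform(_transform_to_sitk_affine(init), inPlace=False)
    return True


def transfer_rois(roi_set: RoiSet, transform: Transform2D, output_shape,
                  pixel_size_um: float) -> RoiSet:
    """Warp MRI-drawn ROI masks onto the histology grid (nearest-neighbour).

    Disjointness is re-checked by the RoiSet constructor; ROIs that land
    empty (e.g. mapped outside the grid) are flagged absent.  If every ROI
    is empty after transfer, an error is raised.
    """
    warped = {}
    absent = []
    for name, mask in roi_set.masks.items():
        out = warp_image(mask, transform, output_shape, interpolation="nearest")
        warped[name] = out
        if not out.any():
            absent.append(name)
            logger.warning("ROI %s is empty after transfer", name)
    if len(absent) == len(warped):
        raise ValueError("all ROIs empty after transfer")
    return RoiSet(masks=warped, grid="HISTOLOGY", pixel_size_um=pixel_size_um,
                  absent=tuple(absent))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
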
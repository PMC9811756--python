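"""Colour deconvolution of brightfield immunostains (hematoxylin + DAB).

Brightfield chromogens obey Beer-Lambert absorption: the optical density
``OD_c = -log10(I_c / I0_c)`` of each RGB channel is linear in the local
chromogen concentrations, ``OD = M @ c``, where the columns of ``M`` are the
unit-norm OD "stain vectors" of hematoxylin, DAB and a residual direction.
Deconvolution inverts this 3x3 system per pixel to obtain per-stain
concentration maps in OD units.  IBA1 and GFAP are both DAB-brown with a
hematoxylin counterstain, so one H-DAB basis serves both; the basis is
configurable when a slide deviates from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging_io import StainImage

logger = logging.getLogger(__name__)

# Classic published H-DAB optical-density basis (unit-normalised below).
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)

STAIN_NAMES = ("hematoxylin", "dab", "residual")


@dataclass(frozen=True)
class StainVectors:
    """3x3 matrix of unit-norm OD column vectors (hematoxylin, DAB, residual)."""

    matrix: np.ndarray
    stain_names: tuple = STAIN_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain columns must be unit-norm, got norms {norms}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-stain concentration rasters (OD units) from one deconvolved image."""

    maps: dict
    pixel_size_um: float
    clipped_fraction: float  # share of |negative| mass removed by clipping

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def default_hdab_vectors() -> StainVectors:
    """The standard H-DAB basis; residual = normalised H x DAB cross product."""
    h = np.array(_HEMATOXYLIN, float)
    d = np.array(_DAB, float)
    h = h / np.linalg.norm(h)
    d = d / np.linalg.norm(d)
    r = np.cross(h, d)
    r = r / np.linalg.norm(r)
    return StainVectors(matrix=np.stack([h, d, r], axis=1))


def vectors_from_config(nine_numbers) -> StainVectors:
    """Build StainVectors from nine numbers (three rows of the matrix)."""
    m = np.asarray(nine_numbers, float).reshape(3, 3)
    m = m / np.linalg.norm(m, axis=0, keepdims=True)
    return StainVectors(matrix=m)


def _as_rgb_float(image) -> np.ndarray:
    if isinstance(image, StainImage):
        image = image.pixels
    arr = np.asarray(image, float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("rgb_to_od requires an RGB image")
    return arr


def rgb_to_od(image, I0=255.0) -> np.ndarray:
    """Convert RGB intensities to optical density: ``-log10(max(I,1)/I0)``.

    ``I0`` is the incident (background) intensity, scalar or per-channel.
    Intensities are floored at 1 so fully absorbed pixels stay finite.
    """
    arr = _as_rgb_float(image)
    I0 = np.broadcast_to(np.asarray(I0, float), (3,))
    if np.any(I0 <= 0) or np.any(I0 > 255):
        raise ValueError("I0 must be in (0, 255] per channel")
    return -np.log10(np.maximum(arr, 1.0) / I0)


def od_to_rgb(od: np.ndarray, I0=255.0, quantize: bool = True) -> np.ndarray:
    """Invert ``rgb_to_od``: ``I = I0 * 10**(-OD)``; optionally round to uint8."""
    I0 = np.broadcast_to(np.asarray(I0, float), (3,))
    rgb = I0 * np.power(10.0, -np.asarray(od, float))
    if quantize:
        return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb


def deconvolve(od: np.ndarray, vectors: StainVectors,
               pixel_size_um: float = 1.0) -> ConcentrationMaps:
    """Unmix a 3-channel OD raster into per-stain concentration maps.

    Solves ``c = M^-1 @ OD`` per pixel.  Negative concentrations (noise or a
    mismatched basis) are clipped to zero; the clipped share of total absolute
    concentration mass is reported as a QC number.
    """
    od = np.asarray(od, float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("OD raster must be HxWx3")
    conc = od @ vectors.inverse.T  # (H, W, 3) in stain order
    neg = np.minimum(conc, 0.0)
    total = float(np.abs(conc).sum())
    clipped = float(-neg.sum()) / total if total > 0 else 0.0
    if clipped > 0.30:
        logger.warning("deconvolution clipped %.1f%% of concentration mass", 100 * clipped)
    conc = np.maximum(conc, 0.0)
    maps = {name: np.ascontiguousarray(conc[:, :, i])
            for i, name in enumerate(vectors.stain_names)}
    return ConcentrationMaps(maps=maps, pixel_size_um=pixel_size_um,
                             clipped_fraction=clipped)


def estimate_i0(image, margin_fraction: float = 0.05,
                percentile: float = 99.0) -> np.ndarray:
    """Estimate per-channel incident intensity from the tissue-free margin.

    Takes the given percentile of each channel over a frame of
    ``margin_fraction`` of the image extent along every border.  Values are
    floored at 1 to keep the OD transform defined.
    """
    arr = _as_rgb_float(image)
    h, w = arr.shape[:2]
    m = max(1, int(round(margin_fraction * min(h, w))))
    frame = np.concatenate([
        arr[:m].reshape(-1, 3),
        arr[-m:].reshape(-1, 3),
        arr[m:-m, :m].reshape(-1, 3),
        arr[m:-m, -m:].reshape(-1, 3),
    ])
    return np.maximum(np.percentile(frame, percentile, axis=0), 1.0)


def separate_image(image: StainImage, vectors: StainVectors | None = None,
                   I0=None) -> ConcentrationMaps:
    """Convenience wrapper: estimate I0 (unless given), OD-transform, unmix."""
    if vectors is None:
        vectors = default_hdab_vectors()
    if I0 is None:
        I0 = estimate_i0(image)
    od = rgb_to_od(image, I0)
    return deconvolve(od, vectors, pixel_size_um=image.pixel_size_um)
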
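"""Image, mask, landmark and cohort-table I/O with unit bookkeeping.

Conventions used throughout the package:

* rasters are 0-based, row-major, origin at the top-left pixel, with pixel
  centres at integer coordinates;
* points are ``(x, y)`` pairs where ``x`` indexes columns and ``y`` rows;
* every physical quantity derives from ``pixel_size_um`` (micrometres per
  pixel edge).  Areas in mm^2 are ``n_pixels * (pixel_size_um / 1000) ** 2``.

Supported on-disk formats are plain 8-bit TIFF and PNG for images and
single-channel masks (nonzero = foreground), and delimited text for the
cohort table and landmark files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

STAIN_KINDS = ("HE", "IBA1_DAB", "GFAP_DAB")
ROI_NAMES = ("NAWM", "WMH")
GRIDS = ("MRI", "HISTOLOGY")

#: default working resolution of the analysis, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 1.0

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "fixation_interval_months",
    "fazekas",
)


@dataclass(frozen=True)
class StainImage:
    """A single brightfield section (RGB) or derived single-channel raster."""

    pixels: np.ndarray
    pixel_size_um: float
    stain_kind: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.size == 0:
            raise ValueError("empty raster")
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"expected 2D or HxWx3 raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError("StainImage pixels must be 8-bit; convert on load")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.stain_kind not in STAIN_KINDS:
            raise ValueError(f"unknown stain_kind {self.stain_kind!r}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass(frozen=True)
class RoiSet:
    """Named binary region masks (NAWM / WMH) on one coordinate grid.

    Masks must share a shape and be pairwise disjoint; a named region that is
    missing on a slide is simply absent from ``masks`` (see ``absent``).
    """

    masks: dict
    grid: str
    pixel_size_um: float
    absent: tuple = ()

    def __post_init__(self) -> None:
        if self.grid not in GRIDS:
            raise ValueError(f"grid must be one of {GRIDS}, got {self.grid!r}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.masks:
            raise ValueError("empty mask set")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"ROI masks disagree in shape: {shapes}")
        names = list(self.masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"ROIs overlap: {a} and {b}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.masks.values())).shape

    def area_mm2(self, name: str) -> float:
        return mask_area_mm2(self.masks[name], self.pixel_size_um)


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member: grouping factor plus the adjustment covariates."""

    subject_id: str
    group: str  # "hypertension" | "control"
    age: float
    sex: str  # "F" | "M"
    fixation_interval_months: float
    fazekas: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("hypertension", "control"):
            raise ValueError(f"{self.subject_id}: group must be hypertension/control")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.subject_id}: sex must be F or M")
        if not self.age > 0:
            raise ValueError(f"{self.subject_id}: age must be positive")
        if self.fazekas not in (0, 1, 2, 3):
            raise ValueError(
                f"subject {self.subject_id}: fazekas must be in 0..3, got {self.fazekas}"
            )


def mask_area_mm2(mask: np.ndarray, pixel_size_um: float) -> float:
    """Physical area of a binary mask in mm^2."""
    return float(np.count_nonzero(mask)) * (pixel_size_um / 1000.0) ** 2


def _read_raster(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def _to_uint8(pixels: np.ndarray, path) -> np.ndarray:
    """Force 8-bit by max-normalised linear rescale (e.g. 16-bit scans)."""
    if pixels.dtype == np.uint8:
        return pixels
    arr = pixels.astype(np.float64)
    peak = arr.max()
    if peak > 0:
        arr = arr / peak * 255.0
    logger.warning("%s: converting %s data to 8-bit by linear rescale", path, pixels.dtype)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def block_average(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Downsample an 8-bit raster by integer block averaging.

    Trailing rows/columns that do not fill a block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return pixels
    h, w = pixels.shape[:2]
    h2, w2 = h // factor, w // factor
    if h2 == 0 or w2 == 0:
        raise ValueError("raster smaller than one block")
    cropped = pixels[: h2 * factor, : w2 * factor]
    if pixels.ndim == 3:
        blocks = cropped.reshape(h2, factor, w2, factor, pixels.shape[2])
        out = blocks.mean(axis=(1, 3))
    else:
        blocks = cropped.reshape(h2, factor, w2, factor)
        out = blocks.mean(axis=(1, 3))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def read_stain_image(
    path,
    pixel_size_um: float,
    stain_kind: str,
    subject_id: str = "",
    working_pixel_size_um: float | None = None,
) -> StainImage:
    """Load a stained section from TIFF/PNG.

    ``pixel_size_um`` is the scan resolution of the file.  If
    ``working_pixel_size_um`` is given and is an integer multiple of the scan
    resolution, the raster is block-averaged down to the working resolution.
    Non-8-bit data are linearly rescaled to 8-bit (with a logged warning).
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    pixels = _to_uint8(_read_raster(path), path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha from PNGs
        pixels = pixels[:, :, :3]
    out_px = pixel_size_um
    if working_pixel_size_um is not None and working_pixel_size_um != pixel_size_um:
        ratio = working_pixel_size_um / pixel_size_um
        factor = int(round(ratio))
        if factor < 1 or abs(ratio - factor) > 1e-9:
            raise ValueError(
                "working_pixel_size_um must be an integer multiple of pixel_size_um"
            )
        pixels = block_average(pixels, factor)
        out_px = working_pixel_size_um
    return StainImage(pixels=pixels, pixel_size_um=out_px, stain_kind=stain_kind,
                      subject_id=subject_id)


def write_stain_image(image: StainImage, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def read_roi_masks(
    paths_by_name: Mapping[str, object],
    grid: str,
    pixel_size_um: float,
) -> RoiSet:
    """Load named ROI masks, binarising at ``value > 0``.

    Raises on shape mismatch or on overlap between named regions; regions
    whose file yields an empty mask are recorded in ``RoiSet.absent``.
    """
    if not paths_by_name:
        raise ValueError("empty mask set")
    masks = {}
    absent = []
    for name, path in paths_by_name.items():
        raw = _read_raster(path)
        if raw.ndim == 3:
            raise ValueError(f"{path}: mask must be single-channel")
        mask = raw > 0
        if mask.any():
            masks[name] = mask
        else:
            absent.append(name)
            masks[name] = mask
    return RoiSet(masks=masks, grid=grid, pixel_size_um=pixel_size_um,
                  absent=tuple(absent))


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_cohort_table(path) -> list:
    """Read the cohort metadata table (CSV/TSV with header) into records.

    Required columns: subject_id, group, age, sex, fixation_interval_months,
    fazekas.  Any further columns are carried along in ``SubjectRecord.extra``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort table") from exc
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: cohort table has no rows")
    extras = [c for c in df.columns if c not in REQUIRED_COHORT_COLUMNS]
    records = []
    for _, row in df.iterrows():
        extra = {c: row[c] for c in extras if pd.notna(row[c])}
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                fixation_interval_months=float(row["fixation_interval_months"]),
                fazekas=int(row["fazekas"]),
                extra=extra,
            )
        )
    return records


def cohort_to_dataframe(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "fixation_interval_months": r.fixation_interval_months,
            "fazekas": r.fazekas,
        }
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def read_landmarks(path) -> tuple:
    """Read paired landmarks: columns name, x_moving, y_moving, x_fixed, y_fixed.

    Returns ``(moving, fixed)`` float arrays of shape (n, 2) in (x, y) order.
    """
    df = pd.read_csv(path)
    needed = ["x_moving", "y_moving", "x_fixed", "y_fixed"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: landmark file missing columns {missing}")
    moving = df[["x_moving", "y_moving"]].to_numpy(float)
    fixed = df[["x_fixed", "y_fixed"]].to_numpy(float)
    return moving, fixed


def write_landmarks(moving: np.ndarray, fixed: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    df = pd.DataFrame(
        {
            "name": [f"L{i}" for i in range(len(moving))],
            "x_moving": moving[:, 0],
            "y_moving": moving[:, 1],
            "x_fixed": fixed[:, 0],
            "y_fixed": fixed[:, 1],
        }
    )
    df.to_csv(path, index=False)
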
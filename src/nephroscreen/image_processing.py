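"""Pre-processing of pronephros z-stacks.

Maximum projection, foreground thresholding with centre-of-mass ROI
detection, fixed-size 257 × 257 thumbnail cropping, and per-plate thumbnail
montages.  All coordinates are 0-based ``(x, y)`` = (column, row) with the
origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "THUMBNAIL_SIZE",
    "ZStack",
    "Thumbnail",
    "NoSignalError",
    "max_project",
    "detect_roi_center",
    "crop_window",
    "crop_thumbnail",
    "make_plate_montage",
]

#: Side length of the square thumbnails cropped around each detected kidney.
THUMBNAIL_SIZE = 257


class NoSignalError(ValueError):
    """Thresholding found no foreground — the well is scored "empty"."""


@dataclass(frozen=True)
class ZStack:
    """A multi-slice fluorescence image of one embryo.

    ``pixels`` is (slices, height, width) of unsigned-integer counts;
    ``slice_spacing_um`` is the focal step between slices.
    """

    pixels: np.ndarray
    channel: str = "GFP"
    slice_spacing_um: float = 15.0

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[0] < 1:
            raise ValueError("stack must be (slices, height, width) with >= 1 slice")
        if not np.issubdtype(px.dtype, np.unsignedinteger):
            raise ValueError(f"stack dtype must be unsigned integer, got {px.dtype}")
        if self.slice_spacing_um < 0:
            raise ValueError("slice spacing must be >= 0")

    @property
    def n_slices(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def shape(self) -> Tuple[int, int]:
        return (int(self.pixels.shape[1]), int(self.pixels.shape[2]))


@dataclass(frozen=True)
class Thumbnail:
    """A 257 × 257 crop around a detected kidney.

    ``center`` is the ROI centre in the source projection, (x, y) pixels.
    """

    pixels: np.ndarray
    well: Optional[object] = None  # a plate_io.WellAddress when known
    center: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.pixels.shape != (THUMBNAIL_SIZE, THUMBNAIL_SIZE):
            raise ValueError(
                f"thumbnail must be {THUMBNAIL_SIZE}x{THUMBNAIL_SIZE}, "
                f"got {self.pixels.shape}"
            )


def max_project(stack: ZStack) -> np.ndarray:
    """Per-pixel maximum over all slices; dtype and XY shape are preserved."""
    return stack.pixels.max(axis=0)


def _percentile_threshold(image: np.ndarray, q: float) -> float:
    return float(np.percentile(image, q))


def detect_roi_center(
    projection: np.ndarray,
    threshold_method: str = "otsu",
    percentile: float = 99.0,
    intensity_weighted: bool = False,
) -> Tuple[int, int]:
    """Locate the kidney as the centroid of the thresholded foreground.

    Parameters
    ----------
    projection
        2-D maximum projection.
    threshold_method
        ``"otsu"`` (default, parameter-free) or ``"percentile"`` with the
        cut at the given intensity percentile.
    intensity_weighted
        When True the centroid is weighted by the foreground intensities;
        the default is the unweighted centroid of the binary mask.

    Returns
    -------
    (x, y) integer pixel coordinates of the centroid.

    Raises
    ------
    NoSignalError
        If the image is uniform or the mask is empty, so callers can record
        the well as "empty".
    """
    img = np.asarray(projection)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("projection must be a non-empty 2-D image")
    if img.min() == img.max():
        raise NoSignalError("uniform image: no foreground signal")
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "percentile":
        thr = _percentile_threshold(img, percentile)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    mask = img > thr
    if not mask.any():
        raise NoSignalError("empty foreground mask after thresholding")
    ys, xs = np.nonzero(mask)
    if intensity_weighted:
        w = img[ys, xs].astype(float)
        cx = float(np.average(xs, weights=w))
        cy = float(np.average(ys, weights=w))
    else:
        cx = float(xs.mean())
        cy = float(ys.mean())
    return (int(round(cx)), int(round(cy)))


def crop_window(
    projection: np.ndarray, center: Tuple[int, int], size: int = THUMBNAIL_SIZE
) -> np.ndarray:
    """Crop a ``size`` × ``size`` window centred on ``center``.

    Regions falling outside the source are zero-padded, so the output shape
    is always exactly ``size`` × ``size`` (half-width ``size // 2`` on each
    side of the centre pixel).  ``size`` must be odd so the centre pixel is
    unambiguous.
    """
    img = np.asarray(projection)
    if img.ndim != 2:
        raise ValueError("projection must be 2-D")
    if size % 2 != 1 or size < 1:
        raise ValueError("crop size must be odd and positive")
    cx, cy = int(center[0]), int(center[1])
    h, w = img.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {center} outside the {w}x{h} projection")
    half = size // 2
    out = np.zeros((size, size), dtype=img.dtype)
    y0, x0 = cy - half, cx - half
    sy0, sy1 = max(y0, 0), min(cy + half + 1, h)
    sx0, sx1 = max(x0, 0), min(cx + half + 1, w)
    out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    return out


def crop_thumbnail(
    projection: np.ndarray, center: Tuple[int, int], well=None
) -> Thumbnail:
    """Crop the standard 257 × 257 thumbnail around the detected ROI centre."""
    pixels = crop_window(projection, center, THUMBNAIL_SIZE)
    return Thumbnail(pixels=pixels, well=well, center=(int(center[0]), int(center[1])))


def make_plate_montage(
    thumbnails: Sequence[Thumbnail],
    layout: Tuple[int, int] = (8, 12),
    rescale: bool = True,
) -> np.ndarray:
    """Tile thumbnails into a plate-layout montage image.

    Tiles are placed by their well address (row letter → grid row, column
    number → grid column); missing wells stay black.  With ``rescale`` the
    montage is display-scaled to the full 16-bit range of its own maximum.
    """
    if not thumbnails:
        raise ValueError("no thumbnails to montage")
    n_rows, n_cols = layout
    size = THUMBNAIL_SIZE
    montage = np.zeros((n_rows * size, n_cols * size), dtype=np.float64)
    seen = set()
    for tn in thumbnails:
        if tn.well is None:
            raise ValueError("montage thumbnails must carry a well address")
        r = ord(str(tn.well.row).upper()) - ord("A")
        c = int(tn.well.column) - 1
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"well {tn.well} outside the {n_rows}x{n_cols} layout")
        if (r, c) in seen:
            raise ValueError(f"duplicate well address {tn.well} in montage")
        seen.add((r, c))
        montage[r * size : (r + 1) * size, c * size : (c + 1) * size] = tn.pixels
    if rescale:
        peak = montage.max()
        if peak > 0:
            montage = montage * (65535.0 / peak)
    return np.clip(montage, 0, 65535).astype(np.uint16)
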
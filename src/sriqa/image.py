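"""Image and mask handling: PNG I/O, ROI geometry around a lesion mask.

Images are 8-bit grayscale rasters (``uint8`` arrays, row-major, 0-based,
row = y, col = x). Lesion masks are boolean arrays of identical shape,
serialized as 0/255 PNGs. The region of interest (ROI) is a half-open
bounding window around the reference lesion mask, padded so that it retains
surrounding tissue — the background needed by the contrast ratio and the
bimodality needed by Otsu thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ROI",
    "EmptyMaskError",
    "DimensionMismatchError",
    "load_gray",
    "load_mask",
    "load_image_pair",
    "save_gray",
    "save_mask",
    "mask_bounding_roi",
    "crop",
]

#: Pixel value at or above which a serialized mask pixel counts as foreground.
#: Tolerates anti-aliased masks produced by external tools.
MASK_THRESHOLD = 128

#: Default fractional padding of the lesion bounding box on each side.
DEFAULT_MARGIN = 0.25


class EmptyMaskError(ValueError):
    """Raised when an operation requires a lesion but the mask is empty.

    Callers routing images through the global/local framework catch this to
    fall back to the global quality path.
    """


class DimensionMismatchError(ValueError):
    """Raised when a paired image and mask differ in shape."""


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular window ``[row_start, row_stop) x [col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop):
            raise ValueError(f"invalid row range [{self.row_start}, {self.row_stop})")
        if not (0 <= self.col_start < self.col_stop):
            raise ValueError(f"invalid col range [{self.col_start}, {self.col_stop})")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    @property
    def area(self) -> int:
        h, w = self.shape
        return h * w


def _to_uint8_gray(img: Image.Image, path: Path | str) -> np.ndarray:
    """Convert a PIL image to a uint8 luminance array."""
    arr = np.asarray(img)
    if arr.dtype == np.uint16 or (arr.dtype.kind in "iu" and arr.dtype.itemsize > 1):
        warnings.warn(
            f"{path}: >8-bit image rescaled to 0..255", UserWarning, stacklevel=3
        )
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        top = arr.max()
        if top > 0:
            arr = arr * (255.0 / top)
        return np.round(arr).astype(np.uint8)
    if img.mode not in ("L",):
        img = img.convert("L")  # ITU-R luminance for color inputs
    return np.asarray(img, dtype=np.uint8)


def load_gray(path: Path | str) -> np.ndarray:
    """Load a PNG as an 8-bit grayscale image array."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as img:
            return _to_uint8_gray(img, path)
    except UnidentifiedImageError as exc:
        raise ValueError(f"{path}: not a readable image file") from exc


def load_mask(path: Path | str) -> np.ndarray:
    """Load a PNG as a boolean lesion mask (value >= 128 -> foreground)."""
    return load_gray(path) >= MASK_THRESHOLD


def load_image_pair(
    image_path: Path | str, mask_path: Path | str
) -> tuple[np.ndarray, np.ndarray]:
    """Load an ultrasound image and its paired lesion mask.

    Returns ``(image, mask)`` where ``image`` is uint8 and ``mask`` boolean,
    both of identical shape.

    Raises
    ------
    FileNotFoundError
        If either file is missing.
    ValueError
        If a file is not a readable image.
    DimensionMismatchError
        If the shapes differ after conversion to single channel.
    """
    image = load_gray(image_path)
    mask = load_mask(mask_path)
    if image.shape != mask.shape:
        raise DimensionMismatchError(
            f"image {image.shape} vs mask {mask.shape} "
            f"({image_path} / {mask_path})"
        )
    return image, mask


def save_gray(image: np.ndarray, path: Path | str) -> None:
    """Write a uint8 grayscale image to PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got {arr.dtype}")
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def save_mask(mask: np.ndarray, path: Path | str) -> None:
    """Write a boolean mask to PNG as 0/255."""
    arr = np.asarray(mask)
    if arr.dtype != np.bool_:
        raise ValueError(f"expected boolean mask, got {arr.dtype}")
    save_gray(arr.astype(np.uint8) * 255, path)


def mask_bounding_roi(mask: np.ndarray, margin_fraction: float = DEFAULT_MARGIN) -> ROI:
    """Padded bounding box of the mask foreground.

    The tight bounding box of the foreground is expanded on each side by
    ``ceil(margin_fraction * extent)`` pixels along the corresponding axis,
    then clipped to the image bounds. The result always contains every
    foreground pixel.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixel (route to global IQA instead).
    """
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pad_r = ceil(margin_fraction * (r1 - r0))
    pad_c = ceil(margin_fraction * (c1 - c0))
    return ROI(
        row_start=max(0, r0 - pad_r),
        row_stop=min(mask.shape[0], r1 + pad_r),
        col_start=max(0, c0 - pad_c),
        col_stop=min(mask.shape[1], c1 + pad_c),
    )


def crop(array: np.ndarray, roi: ROI) -> np.ndarray:
    """Extract the ROI window of an image or mask (copy)."""
    if roi.row_stop > array.shape[0] or roi.col_stop > array.shape[1]:
        raise ValueError(f"ROI {roi} exceeds array shape {array.shape}")
    return array[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop].copy()
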
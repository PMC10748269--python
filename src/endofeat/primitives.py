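"""Core raster types and shared normalization/postprocessing operators.

The package works on three kinds of rasters:

* a *color image* — ``uint8`` array of shape ``(H, W, 3)``, RGB channel order,
  as read from an 8-bit PNG/JPEG/TIFF endoscopic frame;
* a *gray map* — float array of shape ``(H, W)`` with values in ``[0, 1]``,
  the feature activation maps produced by the descriptors;
* a *binary mask* — boolean/0-1 array of shape ``(H, W)``, used both for the
  region-of-interest (visible organ area) and for reference blood-area masks.

Everything downstream (descriptors, fusion, localization) is expressed in
terms of two small operators defined here: a linear range normalization
``norm`` and the map post-processing step ``postprocess_p`` (min-max rescale
followed by binarization at 0.5).
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "InvalidInputError",
    "EmptyRoiError",
    "as_color_image",
    "as_mask",
    "norm",
    "postprocess_p",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_gray_map",
    "read_gray_map",
]


class InvalidInputError(ValueError):
    """Raised when an input violates an operation's contract."""


class EmptyRoiError(InvalidInputError):
    """Raised when a frame contains no detectable organ area."""


def as_color_image(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as an ``(H, W, 3)`` uint8 RGB array."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) color image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidInputError("image must have at least one pixel")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise InvalidInputError("color image must be 8-bit (values in [0, 255])")
    return arr


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and return ``mask`` as an ``(H, W)`` boolean array."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected (H, W) mask, got shape {arr.shape}")
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1, 255))):
            raise InvalidInputError("mask must be binary (0/1 or 0/255)")
        arr = arr > 0
    return arr


def norm(values: np.ndarray | float, lo: float, hi: float) -> np.ndarray | float:
    """Linearly rescale ``values`` so ``[lo, hi] -> [0, 1]`` and clip.

    Computes ``(x - lo) / (hi - lo)`` element-wise, clipped to ``[0, 1]``.
    Order-preserving on ``[lo, hi]``; values at or below ``lo`` map to 0 and
    values at or above ``hi`` map to 1.

    Raises
    ------
    InvalidInputError
        If ``hi <= lo``.
    """
    if hi <= lo:
        raise InvalidInputError(f"norm requires hi > lo, got lo={lo}, hi={hi}")
    scaled = (np.asarray(values, dtype=np.float64) - lo) / (hi - lo)
    out = np.clip(scaled, 0.0, 1.0)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def postprocess_p(activation: np.ndarray) -> np.ndarray:
    """Min-max normalize an activation map to ``[0, 1]`` and threshold at 0.5.

    A constant map has no distinguished pixel and yields the all-zero grid
    (avoids declaring the whole frame a detection).

    Returns a boolean array of the same shape.
    """
    arr = np.asarray(activation, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("activation map must be finite-valued")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=bool)
    return (arr - lo) / (hi - lo) >= 0.5


# ---------------------------------------------------------------------------
# raster I/O

def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB raster (PNG/JPEG/TIFF) as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return as_color_image(np.asarray(im.convert("RGB")))


def write_image(path, img: np.ndarray) -> None:
    Image.fromarray(as_color_image(img), mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Read a single-channel binary mask raster (0 = background)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray((as_mask(mask) * np.uint8(255))).save(path)


def write_gray_map(path, activation: np.ndarray) -> None:
    """Write a [0, 1] activation map as 16-bit grayscale PNG (round(65535*a))."""
    arr = np.asarray(activation, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidInputError("activation map values must lie in [0, 1]")
    q = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(q, mode="I;16").save(path)


def read_gray_map(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back into a [0, 1] float map."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    return arr / 65535.0
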
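"""Region-of-interest detection for endoscopic frames.

Analog endoscopes deliver the organ image inside a bright circular or
rounded-rectangular field of view surrounded by a near-black border, into
which the device prints overlay text (patient id, timestamps).  The color
descriptors must only see the organ area, so every frame is first reduced to
a binary ROI mask.

The algorithm: threshold near-black pixels away, keep the largest connected
bright component (this discards isolated overlay text), morphologically
close it and fill holes (specular highlights, dark pools), then peel dim
transitional pixels off the boundary so that partially-black mixed pixels at
the border never reach the descriptors.  The peel removes only boundary
pixels darker than a brightness floor, which makes the detector a fixed
point under re-application to the masked frame: once every boundary pixel is
bright, nothing more is removed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .primitives import EmptyRoiError, as_color_image

__all__ = ["detect_roi"]

#: intensities at or below this are treated as the black border
BLACK_LEVEL = 12
#: boundary pixels dimmer than this are peeled off as border bleed
DIM_BOUNDARY_LEVEL = 60
#: radius of the elliptical closing kernel (15 px diameter)
CLOSING_RADIUS = 7
#: width of the dim-boundary peel, in pixels
PEEL_WIDTH = 3


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        raise EmptyRoiError("frame is entirely near-black; no organ area found")
    if n == 1:
        return mask
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def detect_roi(img: np.ndarray) -> np.ndarray:
    """Detect the visible-organ mask of an endoscopic frame.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
        RGB endoscopic frame.

    Returns
    -------
    (H, W) bool array
        Connected binary mask covering the bright field of view, excluding
        the near-black border and overlay graphics printed in it.

    Raises
    ------
    EmptyRoiError
        If no pixel exceeds the black level (frame entirely near-black).
    """
    img = as_color_image(img)
    brightness = img.max(axis=2)

    candidate = brightness > BLACK_LEVEL
    if not candidate.any():
        raise EmptyRoiError("frame is entirely near-black; no organ area found")

    mask = _largest_component(candidate)
    # closing; border_value=1 on the erosion so the frame edge is not eroded
    mask = ndi.binary_dilation(mask, structure=disk(CLOSING_RADIUS))
    mask = ndi.binary_erosion(mask, structure=disk(CLOSING_RADIUS), border_value=1)
    mask = ndi.binary_fill_holes(mask)

    # peel dim transitional pixels from the boundary band
    boundary_band = mask & ~ndi.binary_erosion(
        mask, structure=disk(PEEL_WIDTH), border_value=1
    )
    mask = mask & ~(boundary_band & (brightness < DIM_BOUNDARY_LEVEL))

    if not mask.any():
        raise EmptyRoiError("no organ area remains after border removal")
    # peeling can in principle split the region; keep one component
    return _largest_component(mask)
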
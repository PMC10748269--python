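"""Nine hand-crafted visual-feature descriptors of endoscopic bleeding.

Each descriptor transforms an RGB endoscopic frame into a single-channel
*feature activation map* — a grayscale image the size of the frame whose
pixel intensity encodes the local strength of one high-level visual feature
of bleeding.  The nine features are:

F1  blood color region      — narrow blood-red color range (excess of the red
                              channel over green and blue, with green ≈ blue)
F2  smooth blood surface    — F1 regions with a low-variance (liquid) surface
F3  blood region boundary   — F1 regions bounded by a sharp edge
F4  red color region        — like F1 with a wider range of reds accepted
F5  smooth red region       — F2 logic applied to F4
F6  red region boundary     — F3 logic applied to F4
F7  dispersed blood         — small spots/streams of blood color; large
                              connected regions are ignored
F8  red domination          — image-level: fraction of the visible organ area
                              covered by a wide red test, centered so that a
                              map value above 0.5 means red covers > 50%
F9  blur                    — image-level: high color variance combined with
                              a low fraction of edge pixels

F1 follows its published pseudocode exactly: with byte channels r, g, b
(g and b floored at 1 before division),

    c1 = clip((min(r/b, r/g)/255 - 0.003) / (0.01 - 0.003), 0, 1)
    c2 = 1 - |b - g| / 255
    map = clip((c1 * c2^5 - 0.02) / (1.1 - 0.02), 0, 1)
    map[r < 30] = 0;  map[roi == 0] = 0

F2–F9 share F1's style but their numeric parameters were never published;
the defaults in :class:`DescriptorParams` are this package's declared
choices (see docs/methods.md) and every one of them can be overridden.

F8 and F9 are properties of the whole image; they are emitted as
constant-valued maps over the ROI so the 12-channel stacking contract is
uniform across all nine features.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray

from .primitives import InvalidInputError, as_color_image, as_mask, norm

__all__ = [
    "DESCRIPTOR_IDS",
    "DESCRIPTOR_NAMES",
    "DescriptorParams",
    "descriptor_f1",
    "compute_descriptor",
    "compute_all",
]

DESCRIPTOR_IDS = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "F9")

DESCRIPTOR_NAMES = {
    "F1": "blood color region",
    "F2": "blood color region with a smooth surface",
    "F3": "blood region clear boundary",
    "F4": "red color region",
    "F5": "red color region with a smooth surface",
    "F6": "red region clear boundary",
    "F7": "dispersed blood color",
    "F8": "red color domination",
    "F9": "image blur",
}


@dataclass(frozen=True)
class DescriptorParams:
    """Tunable parameters of the nine descriptors.

    F1 parameters are the published values; the rest are declared defaults
    (units: color ratios are byte-ratio/255, intensities and local standard
    deviations are on the 0–255 scale, edge thresholds are intensity change
    per pixel).
    """

    # F1 — blood color region (published)
    f1_c1_lo: float = 0.003
    f1_c1_hi: float = 0.01
    f1_c2_exp: float = 5.0
    f1_map_lo: float = 0.02
    f1_map_hi: float = 1.1
    f1_r_floor: int = 30

    # F4 — red color region (relaxed F1)
    f4_c1_lo: float = 0.0015
    f4_c1_hi: float = 0.01
    f4_c2_exp: float = 2.0
    f4_r_floor: int = 30

    # F2/F5 — surface smoothness gate
    smooth_window: int = 11
    smooth_std_lo: float = 2.0
    smooth_std_hi: float = 30.0

    # F3/F6 — clear-boundary test
    region_threshold: float = 0.5
    boundary_edge_threshold: float = 30.0
    boundary_min_fraction: float = 0.2

    # F7 — dispersed blood
    f7_color_threshold: float = 0.5
    f7_max_area_fraction: float = 0.01

    # F8 — red domination
    f8_red_margin: int = 20
    f8_highlight_level: int = 230
    f8_dark_level: int = 30
    f8_lo: float = 0.25
    f8_hi: float = 0.75

    # F9 — blur
    f9_var_lo: float = 50.0
    f9_var_hi: float = 1500.0
    f9_edge_threshold: float = 40.0
    f9_edge_lo: float = 0.01
    f9_edge_hi: float = 0.12

    def replace(self, **overrides) -> "DescriptorParams":
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise InvalidInputError(f"unknown descriptor parameters: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)


DEFAULT_PARAMS = DescriptorParams()


def _check_shapes(img: np.ndarray, roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    img = as_color_image(img)
    roi = as_mask(roi)
    if img.shape[:2] != roi.shape:
        raise InvalidInputError(
            f"image {img.shape[:2]} and roi {roi.shape} shapes differ"
        )
    return img, roi


def _excess_red_map(
    img: np.ndarray,
    roi: np.ndarray,
    *,
    c1_lo: float,
    c1_hi: float,
    c2_exp: float,
    map_lo: float,
    map_hi: float,
    r_floor: int,
) -> np.ndarray:
    """Shared excess-red color pipeline behind F1 and F4."""
    rgb = img.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    g = np.maximum(g, 1.0)
    b = np.maximum(b, 1.0)

    c1 = np.minimum(r / b, r / g) / 255.0
    c1 = np.maximum(c1, 0.0)
    c1 = norm(c1, c1_lo, c1_hi)

    c2 = 1.0 - np.abs(b - g) / 255.0

    feature_map = norm(c1 * c2**c2_exp, map_lo, map_hi)
    feature_map[rgb[..., 0] < r_floor] = 0.0
    feature_map[~roi] = 0.0
    return feature_map


def descriptor_f1(
    img: np.ndarray, roi: np.ndarray, params: DescriptorParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Blood color region activation map (F1), per the published pseudocode."""
    img, roi = _check_shapes(img, roi)
    return _excess_red_map(
        img,
        roi,
        c1_lo=params.f1_c1_lo,
        c1_hi=params.f1_c1_hi,
        c2_exp=params.f1_c2_exp,
        map_lo=params.f1_map_lo,
        map_hi=params.f1_map_hi,
        r_floor=params.f1_r_floor,
    )


def _descriptor_f4(img, roi, params):
    return _excess_red_map(
        img,
        roi,
        c1_lo=params.f4_c1_lo,
        c1_hi=params.f4_c1_hi,
        c2_exp=params.f4_c2_exp,
        map_lo=params.f1_map_lo,
        map_hi=params.f1_map_hi,
        r_floor=params.f4_r_floor,
    )


def _gray255(img: np.ndarray) -> np.ndarray:
    return rgb2gray(img) * 255.0


def _local_std(gray: np.ndarray, window: int) -> np.ndarray:
    mean = ndi.uniform_filter(gray, size=window, mode="reflect")
    mean_sq = ndi.uniform_filter(gray * gray, size=window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def _smoothness(gray: np.ndarray, params: DescriptorParams) -> np.ndarray:
    """1 where the local gray surface is flat, 0 where it is strongly textured."""
    std = _local_std(gray, params.smooth_window)
    return 1.0 - norm(std, params.smooth_std_lo, params.smooth_std_hi)


def _edge_magnitude(gray: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude in intensity-change-per-pixel units."""
    gx = ndi.sobel(gray, axis=1, mode="reflect") / 8.0
    gy = ndi.sobel(gray, axis=0, mode="reflect") / 8.0
    return np.hypot(gx, gy)


def _boundary_gated(base: np.ndarray, gray: np.ndarray, roi: np.ndarray,
                    params: DescriptorParams) -> np.ndarray:
    """Keep base-map regions whose contour is sharp (F3/F6 logic).

    Regions are connected components of the base activation above the region
    threshold.  A region survives when at least ``boundary_min_fraction`` of
    its contour-band pixels carry a Sobel edge above the edge threshold; the
    surviving region is painted with its own activation so the map marks
    where the blood is, not just its rim.
    """
    regions = base >= params.region_threshold
    out = np.zeros_like(base)
    labels, n = ndi.label(regions)
    if n == 0:
        return out
    strong = _edge_magnitude(gray) > params.boundary_edge_threshold
    for i in range(1, n + 1):
        comp = labels == i
        band = ndi.binary_dilation(comp) & ~ndi.binary_erosion(comp)
        band &= roi
        if not band.any():
            continue
        if strong[band].mean() >= params.boundary_min_fraction:
            out[comp] = base[comp]
    out[~roi] = 0.0
    return out


def _descriptor_f7(f1_map: np.ndarray, roi: np.ndarray, params: DescriptorParams) -> np.ndarray:
    """Blood-colored pixels excluding large connected areas."""
    colored = f1_map >= params.f7_color_threshold
    labels, n = ndi.label(colored)
    out = np.zeros_like(f1_map)
    if n == 0:
        return out
    max_area = params.f7_max_area_fraction * roi.sum()
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep_labels = np.flatnonzero(sizes <= max_area) + 1
    keep = np.isin(labels, keep_labels)
    out[keep] = f1_map[keep]
    return out


def _descriptor_f8(img: np.ndarray, roi: np.ndarray, params: DescriptorParams) -> np.ndarray:
    """Red-domination constant map: > 0.5 iff red covers > 50% of the clear ROI."""
    rgb = img.astype(np.int16)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    highlight = rgb.min(axis=2) > params.f8_highlight_level
    dark = rgb.max(axis=2) < params.f8_dark_level
    valid = roi & ~highlight & ~dark
    if valid.any():
        red = (r > g + params.f8_red_margin) & (r > b + params.f8_red_margin)
        fraction = float(red[valid].mean())
    else:
        fraction = 0.0
    value = norm(fraction, params.f8_lo, params.f8_hi)
    out = np.zeros(roi.shape, dtype=np.float64)
    out[roi] = value
    return out


def _descriptor_f9(img: np.ndarray, gray: np.ndarray, roi: np.ndarray,
                   params: DescriptorParams) -> np.ndarray:
    """Blur constant map: high color variance combined with few edges."""
    rgb = img.astype(np.float64)
    variance = float(np.mean([rgb[..., c][roi].var() for c in range(3)]))
    edges = _edge_magnitude(gray) > params.f9_edge_threshold
    edge_fraction = float(edges[roi].mean())
    value = norm(variance, params.f9_var_lo, params.f9_var_hi) * (
        1.0 - norm(edge_fraction, params.f9_edge_lo, params.f9_edge_hi)
    )
    out = np.zeros(roi.shape, dtype=np.float64)
    out[roi] = value
    return out


def compute_descriptor(
    descriptor_id: str,
    img: np.ndarray,
    roi: np.ndarray,
    params: DescriptorParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Compute one feature activation map.

    Parameters
    ----------
    descriptor_id : str
        One of ``"F1"`` … ``"F9"``.
    img : (H, W, 3) uint8 array
    roi : (H, W) binary mask
    params : DescriptorParams

    Returns
    -------
    (H, W) float array in [0, 1], zero outside ``roi``.
    """
    if descriptor_id not in DESCRIPTOR_IDS:
        raise InvalidInputError(f"unknown descriptor id: {descriptor_id!r}")
    img, roi = _check_shapes(img, roi)

    if descriptor_id in ("F2", "F3", "F5", "F6", "F9"):
        gray = _gray255(img)
    if descriptor_id in ("F1", "F2", "F3", "F7"):
        f1 = descriptor_f1(img, roi, params)
    if descriptor_id in ("F4", "F5", "F6"):
        f4 = _descriptor_f4(img, roi, params)

    if descriptor_id == "F1":
        return f1
    if descriptor_id == "F2":
        return f1 * _smoothness(gray, params)
    if descriptor_id == "F3":
        return _boundary_gated(f1, gray, roi, params)
    if descriptor_id == "F4":
        return f4
    if descriptor_id == "F5":
        return f4 * _smoothness(gray, params)
    if descriptor_id == "F6":
        return _boundary_gated(f4, gray, roi, params)
    if descriptor_id == "F7":
        return _descriptor_f7(f1, roi, params)
    if descriptor_id == "F8":
        return _descriptor_f8(img, roi, params)
    return _descriptor_f9(img, _gray255(img), roi, params)


def compute_all(
    img: np.ndarray, roi: np.ndarray, params: DescriptorParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Compute the full feature stack: an (H, W, 9) array, channel c = F(c+1).

    Shares the F1/F4 color maps, grayscale conversion and smoothness gate
    between features instead of recomputing them per channel.
    """
    img, roi = _check_shapes(img, roi)
    gray = _gray255(img)
    f1 = descriptor_f1(img, roi, params)
    f4 = _descriptor_f4(img, roi, params)
    smooth = _smoothness(gray, params)

    channels = [
        f1,
        f1 * smooth,
        _boundary_gated(f1, gray, roi, params),
        f4,
        f4 * smooth,
        _boundary_gated(f4, gray, roi, params),
        _descriptor_f7(f1, roi, params),
        _descriptor_f8(img, roi, params),
        _descriptor_f9(img, gray, roi, params),
    ]
    stack = np.stack(channels, axis=-1)
    stack[~roi] = 0.0
    return stack
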
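"""Weakly supervised bleeding localization and bounding-box IoU evaluation.

The feature descriptors alone already localize bleeding: averaging the
activations of the seven spatial features F1-F7 and binarizing the result
(min-max normalize, threshold at 0.5) yields a location map without any
neural-network inference — the *Fmap* method.  Saliency maps obtained from
a trained classifier (Grad-CAM and relatives) can be fused with the Fmap by
averaging the 0-1 normalized maps before binarization.

Predicted locations are scored against annotated blood-area masks by the
intersection-over-union of their tight axis-aligned bounding boxes,

    IoU = area(pred_box ∩ mask_box) / area(pred_box ∪ mask_box),

which is robust to the coarse resolution of saliency-based predictions.
Boxes use 0-based half-open pixel coordinates, so the area of
``(r0, c0, r1, c1)`` is exactly ``(r1 - r0) * (c1 - c0)``.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .primitives import InvalidInputError, as_mask, postprocess_p

__all__ = [
    "BoundingBox",
    "fmap_localize",
    "combine_maps",
    "mask_to_bbox",
    "iou",
    "evaluate_localization",
]


class BoundingBox(NamedTuple):
    """Half-open pixel rectangle [row0, row1) x [col0, col1), 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def fmap_localize(feats: np.ndarray) -> np.ndarray:
    """Predict a bleeding-location mask from the feature stack alone.

    Averages channels F1..F7 (the spatial features) and applies the
    normalize-and-threshold postprocessing.  Returns a boolean (H, W) grid.
    """
    feats = np.asarray(feats, dtype=np.float64)
    if feats.ndim != 3 or feats.shape[2] != 9:
        raise InvalidInputError(f"expected (H, W, 9) feature stack, got {feats.shape}")
    mean_map = feats[..., :7].mean(axis=2)
    return postprocess_p(mean_map)


def combine_maps(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fuse two activation maps (e.g. a saliency map with the Fmap).

    Each map is min-max normalized to [0, 1]; the fused map is their mean,
    binarized with the normalize-and-threshold postprocessing.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"map shapes differ: {a.shape} vs {b.shape}")
    return postprocess_p((_minmax(a) + _minmax(b)) / 2.0)


def mask_to_bbox(mask: np.ndarray) -> Optional[BoundingBox]:
    """Tight bounding box of all nonzero pixels; ``None`` for an empty grid."""
    mask = as_mask(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ih = min(a.row1, b.row1) - max(a.row0, b.row0)
    iw = min(a.col1, b.col1) - max(a.col0, b.col0)
    inter = max(ih, 0) * max(iw, 0)
    union = a.area + b.area - inter
    return inter / union


def evaluate_localization(
    predictions: Sequence[np.ndarray],
    references: Sequence[np.ndarray],
    image_ids: Optional[Sequence[str]] = None,
) -> tuple[float, pd.DataFrame]:
    """Score predicted location masks against reference blood-area masks.

    Per image, the IoU of the tight bounding boxes is computed; an empty
    prediction against a non-empty reference scores 0, and empty against
    empty scores 1 (nothing to find, nothing found).

    Returns
    -------
    mean_iou : float
    table : DataFrame with columns ``image_id`` and ``iou``.
    """
    if len(predictions) != len(references):
        raise InvalidInputError(
            f"{len(predictions)} predictions vs {len(references)} references"
        )
    if image_ids is None:
        image_ids = [str(i) for i in range(len(predictions))]
    rows = []
    for img_id, pred, ref in zip(image_ids, predictions, references):
        pbox = mask_to_bbox(pred)
        rbox = mask_to_bbox(ref)
        if pbox is None and rbox is None:
            value = 1.0
        elif pbox is None or rbox is None:
            value = 0.0
        else:
            value = iou(pbox, rbox)
        rows.append({"image_id": img_id, "iou": value})
    table = pd.DataFrame(rows, columns=["image_id", "iou"])
    mean_iou = float(table["iou"].mean()) if len(table) else float("nan")
    return mean_iou, table
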
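"""Independent reference implementations used to cross-check the package.

Everything here is written as a literal, unvectorized trace of the
definitions (per-pixel loops, pixel-set enumeration, pairwise comparison,
exhaustive threshold sweeps) and deliberately shares no code with the
implementation it checks.
"""

import numpy as np


def f1_scalar(r: int, g: int, b: int, roi: int) -> float:
    """Per-pixel trace of the blood-color-region descriptor pseudocode."""
    g = max(g, 1)
    b = max(b, 1)
    c1 = min(r / b, r / g) / 255.0
    c1 = max(c1, 0.0)
    c1 = min(max((c1 - 0.003) / (0.01 - 0.003), 0.0), 1.0)
    c2 = 1.0 - abs(b - g) / 255.0
    fm = c1 * c2**5
    fm = min(max((fm - 0.02) / (1.1 - 0.02), 0.0), 1.0)
    if r < 30:
        fm = 0.0
    if roi == 0:
        fm = 0.0
    return fm


def f1_image_loop(img: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Pixel-by-pixel loop application of :func:`f1_scalar`."""
    h, w = roi.shape
    out = np.empty((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            r, g, b = (int(v) for v in img[y, x])
            out[y, x] = f1_scalar(r, g, b, int(roi[y, x]))
    return out


def box_iou_pixelset(a, b, shape) -> float:
    """IoU of two half-open boxes by painting and counting pixel sets."""
    ga = np.zeros(shape, dtype=bool)
    gb = np.zeros(shape, dtype=bool)
    ga[a[0]: a[2], a[1]: a[3]] = True
    gb[b[0]: b[2], b[1]: b[3]] = True
    inter = int((ga & gb).sum())
    union = int((ga | gb).sum())
    return inter / union


def bbox_scan(mask: np.ndarray):
    """Brute-force min/max scan for the tight bounding box of a mask."""
    coords = [(y, x) for y in range(mask.shape[0]) for x in range(mask.shape[1]) if mask[y, x]]
    if not coords:
        return None
    rows = [c[0] for c in coords]
    cols = [c[1] for c in coords]
    return (min(rows), min(cols), max(rows) + 1, max(cols) + 1)


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(equal) over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(pos) * len(neg)))


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """All (fpr, tpr) operating points over every achievable threshold."""
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    points = []
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        points.append((fp / n_neg, tp / n_pos))
    return points


def sens_at_fpr_sweep(scores, labels, fpr: float) -> float:
    pts = _sweep(np.asarray(scores), np.asarray(labels))
    ok = [tpr for f, tpr in pts if f <= fpr]
    return max(ok) if ok else 0.0


def spec_at_sens_sweep(scores, labels, sens: float) -> float:
    pts = _sweep(np.asarray(scores), np.asarray(labels))
    ok = [1.0 - f for f, tpr in pts if tpr >= sens]
    return max(ok) if ok else 0.0
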
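"""Dataset balancing, examination-level fold assignment, and augmentation.

Endoscopic datasets are annotated as *samples*: short video clips extracted
from an *examination*, labelled blood or non-blood.  The number of frames
per sample is strongly imbalanced (many samples hold a single frame, some
hold thousands), so blood samples are balanced up to a minimum image count
by cyclic duplication; non-blood samples are left untouched.  Cross-
validation folds are assigned at the examination level so that no frames of
one examination ever appear in two folds.

The augmentation battery covers geometric transforms (rotation, flips,
skew, perspective) and photometric ones (Gaussian blur, additive noise, hue
and saturation distortion, PCA color augmentation), each with a magnitude
drawn uniformly from a configured range on every application.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from .primitives import InvalidInputError, as_color_image

__all__ = [
    "SampleRecord",
    "AugmentationConfig",
    "balance_positive_samples",
    "make_folds",
    "augment",
    "records_to_manifest",
    "manifest_to_records",
]


@dataclass
class SampleRecord:
    """One annotated video-clip sample: a labelled, ordered set of frames."""

    sample_id: str
    exam_id: str
    label: str  # "blood" or "non-blood"
    image_refs: list[str]

    def __post_init__(self):
        if self.label not in ("blood", "non-blood"):
            raise InvalidInputError(f"label must be blood/non-blood, got {self.label!r}")
        if not self.image_refs:
            raise InvalidInputError("a sample must reference at least one image")


def balance_positive_samples(
    records: list[SampleRecord], min_images: int = 100
) -> list[SampleRecord]:
    """Duplicate images of small blood samples up to ``min_images``.

    Duplication is cyclic over the sample's own images; non-blood samples
    are returned unchanged and no image is ever removed.
    """
    out = []
    for rec in records:
        refs = rec.image_refs
        if rec.label == "blood" and len(refs) < min_images:
            reps = -(-min_images // len(refs))  # ceil
            refs = (refs * reps)[:min_images]
        out.append(dataclasses.replace(rec, image_refs=list(refs)))
    return out


def make_folds(records: list[SampleRecord], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Randomly partition examinations into ``k`` folds.

    Returns a mapping exam_id -> fold index in [0, k).  All samples (and
    hence all images) of one examination share a fold.
    """
    exams = sorted({rec.exam_id for rec in records})
    if len(exams) < k:
        raise InvalidInputError(f"{len(exams)} exams cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exams))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[exams[idx]] = fold
    return assignment


@dataclass
class AugmentationConfig:
    """Enable flags and magnitude ranges of the augmentation battery.

    Ranges are closed intervals; a magnitude is drawn uniformly from its
    range on each application.  Angles are in degrees, blur sigma in pixels,
    noise std on the 0-255 intensity scale, hue shift in degrees on the
    color circle, saturation as a multiplicative factor, and the PCA color
    scale is the std of the eigen-perturbation coefficients.
    """

    rotation: bool = True
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    skew: bool = True
    skew_range: tuple[float, float] = (-0.1, 0.1)
    perspective: bool = True
    perspective_range: tuple[float, float] = (0.0, 0.05)
    blur: bool = True
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    noise: bool = True
    noise_std_range: tuple[float, float] = (0.0, 8.0)
    hue: bool = True
    hue_shift_range: tuple[float, float] = (-10.0, 10.0)
    saturation: bool = True
    saturation_range: tuple[float, float] = (0.8, 1.2)
    pca_color: bool = True
    pca_scale_range: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name.endswith(("_range",)):
                lo, hi = getattr(self, f.name)
                if hi < lo:
                    raise InvalidInputError(f"{f.name} is not a valid interval: ({lo}, {hi})")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        flags = {f.name: False for f in dataclasses.fields(cls) if not f.name.endswith("_range")}
        return cls(**flags)


def _warp_uint8(img: np.ndarray, transform) -> np.ndarray:
    out = warp(img.astype(np.float64), transform, mode="edge", order=1, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _pca_color_shift(img: np.ndarray, scale: float, rng) -> np.ndarray:
    """Eigen-perturbation of the per-image RGB covariance (AlexNet-style)."""
    flat = img.reshape(-1, 3).astype(np.float64) / 255.0
    cov = np.cov(flat, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    alpha = rng.normal(0.0, scale, size=3)
    shift = eigvec @ (alpha * eigval)
    return img.astype(np.float64) + shift * 255.0


def augment(img: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Apply the configured augmentation battery, deterministic under ``seed``.

    With every transform disabled this is the exact identity.
    """
    img = as_color_image(img)
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    center = np.array([w, h]) / 2.0

    if cfg.rotation:
        angle = np.deg2rad(rng.uniform(*cfg.rotation_range))
        t = (AffineTransform(translation=-center)
             + AffineTransform(rotation=angle)
             + AffineTransform(translation=center))
        img = _warp_uint8(img, t.inverse)
    if cfg.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        img = img[::-1]
    if cfg.skew:
        shear = rng.uniform(*cfg.skew_range)
        t = (AffineTransform(translation=-center)
             + AffineTransform(shear=shear)
             + AffineTransform(translation=center))
        img = _warp_uint8(img, t.inverse)
    if cfg.perspective:
        mag = rng.uniform(*cfg.perspective_range)
        src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=np.float64)
        jitter = rng.uniform(-mag, mag, size=(4, 2)) * [w, h]
        t = ProjectiveTransform()
        t.estimate(src + jitter, src)
        img = _warp_uint8(img, t)
    if cfg.blur:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        if sigma > 0:
            blurred = ndi.gaussian_filter(img.astype(np.float64), sigma=(sigma, sigma, 0))
            img = np.clip(np.round(blurred), 0, 255).astype(np.uint8)
    if cfg.noise:
        std = rng.uniform(*cfg.noise_std_range)
        if std > 0:
            noisy = img.astype(np.float64) + rng.normal(0.0, std, img.shape)
            img = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    if cfg.hue or cfg.saturation:
        hsv = rgb2hsv(img)
        if cfg.hue:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(*cfg.hue_shift_range) / 360.0) % 1.0
        if cfg.saturation:
            hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*cfg.saturation_range), 0, 1)
        img = np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    if cfg.pca_color:
        scale = rng.uniform(*cfg.pca_scale_range)
        if scale > 0:
            img = np.clip(np.round(_pca_color_shift(img, scale, rng)), 0, 255).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# manifest I/O (one CSV row per image reference)

def records_to_manifest(records: list[SampleRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "exam_id": r.exam_id, "label": r.label, "image_path": ref}
        for r in records
        for ref in r.image_refs
    ]
    return pd.DataFrame(rows, columns=["sample_id", "exam_id", "label", "image_path"])


def manifest_to_records(manifest: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for sample_id, group in manifest.groupby("sample_id", sort=False):
        exams = group["exam_id"].unique()
        labels = group["label"].unique()
        if len(exams) != 1 or len(labels) != 1:
            raise InvalidInputError(f"sample {sample_id}: mixed exam_id or label")
        records.append(
            SampleRecord(str(sample_id), str(exams[0]), str(labels[0]),
                         group["image_path"].tolist())
        )
    return records
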
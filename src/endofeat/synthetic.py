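"""Seeded synthetic endoscopic frames with exact ground-truth masks.

The generator emulates the geometry and photometry of analog endoscopic
video frames as far as the color descriptors care about them: a bright
circular (or rounded-rectangular) field of view on a near-black border with
overlay-like bright text printed in the border, a pink mucosa background
with low-frequency texture, elliptical blood pools whose color has high
red-to-green and red-to-blue ratios and a near-equal green/blue pair,
orange-red distractor regions (a wider, less blood-typical red), specular
highlights, bubble rings and optional global blur.

Every frame comes with its exact blood mask (union of the blood ellipses)
and exact field-of-view mask, so descriptor, ROI and localization behavior
can be tested without any real dataset.  Rendering is fully deterministic
under the scene seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .dataprep import SampleRecord, records_to_manifest
from .primitives import InvalidInputError, write_image, write_mask

__all__ = [
    "Ellipse",
    "Highlight",
    "Bubble",
    "TextBlock",
    "SceneSpec",
    "generate_frame",
    "random_scene",
    "generate_dataset",
]

#: default blood color — r/g ~ 6.8, r/b ~ 5.4, |g-b| = 6: firmly inside the
#: narrow blood-red range of the F1 descriptor
BLOOD_COLOR = (150, 22, 28)
#: default mucosa color — a mild red excess (r/g ~ 1.5) typical of healthy tissue
MUCOSA_COLOR = (185, 125, 105)
#: default distractor color — orange-red with a wide green/blue gap (F4 range)
DISTRACTOR_COLOR = (180, 100, 50)


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: center (row, col), semi-axes (a_row, a_col), angle in degrees."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float = 0.0
    color: tuple[int, int, int] = BLOOD_COLOR
    noise_std: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        t = np.deg2rad(self.angle)
        u = dr * np.cos(t) + dc * np.sin(t)
        v = -dr * np.sin(t) + dc * np.cos(t)
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class Highlight:
    """Specular reflection: a near-saturated disc."""

    center: tuple[float, float]
    radius: float
    color: tuple[int, int, int] = (245, 245, 245)


@dataclass(frozen=True)
class Bubble:
    """Bubble rendered as a bright thin ring."""

    center: tuple[float, float]
    radius: float
    width: float = 2.0


@dataclass(frozen=True)
class TextBlock:
    """Overlay-like bright block printed in the black border (row, col, h, w)."""

    row: int
    col: int
    height: int = 10
    width: int = 50


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic endoscopic frame."""

    shape: tuple[int, int] = (576, 720)  # (H, W): PAL frame
    fov_shape: str = "disc"  # "disc" or "rounded_rect"
    fov_center: tuple[float, float] | None = None
    fov_radius: float | None = None
    mucosa_color: tuple[int, int, int] = MUCOSA_COLOR
    texture_noise_std: float = 6.0
    texture_smoothing: float = 6.0
    blood_blobs: tuple[Ellipse, ...] = ()
    distractor_blobs: tuple[Ellipse, ...] = ()
    highlights: tuple[Highlight, ...] = ()
    bubbles: tuple[Bubble, ...] = ()
    blur_sigma: float = 0.0
    text_blocks: tuple[TextBlock, ...] = ()
    seed: int = 0

    def resolved_fov(self) -> tuple[tuple[float, float], float]:
        h, w = self.shape
        center = self.fov_center if self.fov_center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        radius = self.fov_radius if self.fov_radius is not None else 0.45 * min(h, w)
        return center, radius


def _fov_mask(spec: SceneSpec) -> np.ndarray:
    (cr, cc), radius = spec.resolved_fov()
    rr, col = np.mgrid[: spec.shape[0], : spec.shape[1]]
    if spec.fov_shape == "disc":
        return (rr - cr) ** 2 + (col - cc) ** 2 <= radius**2
    if spec.fov_shape == "rounded_rect":
        # rectangle of half-extent 1.3R x 1.0R with corner radius 0.4R
        hr, wr, corner = radius, 1.3 * radius, 0.4 * radius
        dr = np.abs(rr - cr) - (hr - corner)
        dc = np.abs(col - cc) - (wr - corner)
        outside = np.hypot(np.maximum(dr, 0), np.maximum(dc, 0))
        return outside <= corner
    raise InvalidInputError(f"unknown fov shape: {spec.fov_shape!r}")


def generate_frame(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a scene.

    Returns
    -------
    image : (H, W, 3) uint8
    blood_mask : (H, W) bool — exact union of the blood ellipses
    roi_mask : (H, W) bool — exact field-of-view mask
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    fov = _fov_mask(spec)

    img = np.zeros((h, w, 3), dtype=np.float64)
    base = np.array(spec.mucosa_color, dtype=np.float64)
    img[fov] = base

    if spec.texture_noise_std > 0:
        noise = rng.normal(0.0, 1.0, (h, w))
        if spec.texture_smoothing > 0:
            noise = ndi.gaussian_filter(noise, spec.texture_smoothing)
            sd = noise.std()
            if sd > 0:
                noise /= sd
        img[fov] += (noise[fov] * spec.texture_noise_std)[:, None]

    blood_mask = np.zeros((h, w), dtype=bool)

    def paint(blob: Ellipse) -> np.ndarray:
        m = blob.mask(spec.shape)
        if not m.any():
            raise InvalidInputError("blob renders no pixels")
        if (m & ~fov).any():
            raise InvalidInputError("blob extends outside the field of view")
        img[m] = np.array(blob.color, dtype=np.float64)
        if blob.noise_std > 0:
            img[m] += rng.normal(0.0, blob.noise_std, (int(m.sum()), 3))
        return m

    for blob in spec.blood_blobs:
        blood_mask |= paint(blob)
    for blob in spec.distractor_blobs:
        paint(blob)

    rr, cc = np.mgrid[:h, :w]
    for hl in spec.highlights:
        m = (rr - hl.center[0]) ** 2 + (cc - hl.center[1]) ** 2 <= hl.radius**2
        img[m & fov] = np.array(hl.color, dtype=np.float64)
    for bub in spec.bubbles:
        d = np.hypot(rr - bub.center[0], cc - bub.center[1])
        ring = np.abs(d - bub.radius) <= bub.width / 2.0
        img[ring & fov] = np.array((235, 235, 230), dtype=np.float64)

    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
        img[~fov] = 0.0  # keep the border crisp, as the device mask does

    for block in spec.text_blocks:
        sl = (slice(block.row, block.row + block.height),
              slice(block.col, block.col + block.width))
        if fov[sl].any():
            raise InvalidInputError("overlay text block overlaps the field of view")
        # dashed fill to mimic character strokes
        patch = np.zeros((block.height, block.width), dtype=bool)
        patch[:, :: 3] = True
        patch[:, 1:: 3] = True
        region = img[sl]
        region[patch] = 235.0
        img[sl] = region

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return image, blood_mask, fov


def random_scene(
    seed: int,
    with_blood: bool,
    shape: tuple[int, int] = (576, 720),
    crisp: bool = False,
) -> SceneSpec:
    """Draw a randomized scene: jittered field of view, mucosa tint, blobs.

    ``crisp`` restricts the scene to a single clean blood ellipse with no
    highlights, bubbles or blur — the configuration used to measure
    localization recovery.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    radius = rng.uniform(0.38, 0.46) * min(h, w)
    center = (h / 2 + rng.uniform(-8, 8), w / 2 + rng.uniform(-8, 8))
    mucosa = tuple(
        int(np.clip(c + rng.integers(-10, 11), 0, 255)) for c in MUCOSA_COLOR
    )

    def inner_point(margin):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, radius - margin)
        return (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))

    blood = ()
    if with_blood:
        n = 1 if crisp else rng.integers(1, 3)
        blobs = []
        for _ in range(int(n)):
            axes = (rng.uniform(0.2, 0.42) * radius, rng.uniform(0.2, 0.42) * radius)
            blobs.append(
                Ellipse(
                    center=inner_point(margin=max(axes) + 4),
                    axes=axes,
                    angle=rng.uniform(0, 180),
                    color=tuple(
                        int(np.clip(c + rng.integers(-6, 7), 0, 255)) for c in BLOOD_COLOR
                    ),
                )
            )
        blood = tuple(blobs)

    highlights = ()
    bubbles = ()
    distractors = ()
    if not crisp:
        if rng.random() < 0.5:
            highlights = (Highlight(center=inner_point(0.16 * radius),
                                    radius=rng.uniform(0.03, 0.08) * radius),)
        if rng.random() < 0.3:
            bubbles = (Bubble(center=inner_point(0.2 * radius),
                              radius=rng.uniform(0.06, 0.13) * radius),)
        if rng.random() < 0.4:
            ax = (rng.uniform(0.12, 0.24) * radius, rng.uniform(0.12, 0.24) * radius)
            distractors = (
                Ellipse(center=inner_point(max(ax) + 4), axes=ax,
                        color=DISTRACTOR_COLOR),
            )

    text = (TextBlock(row=4, col=4),) if min(center[0] - radius, center[1] - radius) > 18 else ()

    return SceneSpec(
        shape=shape,
        fov_center=center,
        fov_radius=radius,
        mucosa_color=mucosa,
        blood_blobs=blood,
        distractor_blobs=distractors,
        highlights=highlights,
        bubbles=bubbles,
        text_blocks=text,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    out_dir,
    n_blood: int,
    n_normal: int,
    seed: int = 0,
    shape: tuple[int, int] = (576, 720),
    images_per_sample: tuple[int, ...] = (1, 2, 3, 5),
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Write a synthetic dataset: frames, masks, and a sample manifest CSV.

    Frames are grouped into synthetic samples (image counts drawn from
    ``images_per_sample``) and exams of up to two samples each, so the
    balancing and fold-assignment machinery can be exercised end to end.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    records = []
    counts = {"blood": n_blood, "non-blood": n_normal}
    sample_idx = 0
    for label, count in counts.items():
        remaining = count
        while remaining > 0:
            size = min(int(rng.choice(images_per_sample)), remaining)
            sample_id = f"sample{sample_idx:04d}"
            exam_id = f"exam{sample_idx // 2:04d}"
            refs = []
            for i in range(size):
                scene = random_scene(
                    int(rng.integers(0, 2**31 - 1)), with_blood=(label == "blood"),
                    shape=shape,
                )
                image, blood_mask, _roi = generate_frame(scene)
                name = f"{sample_id}_{i:03d}.png"
                write_image(out_dir / "images" / name, image)
                write_mask(out_dir / "masks" / name, blood_mask)
                refs.append(f"images/{name}")
            records.append(SampleRecord(sample_id, exam_id, label, refs))
            sample_idx += 1
            remaining -= size

    manifest = records_to_manifest(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return records, manifest
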
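"""Assembling the 12-channel CNN input and related model plumbing.

A feature-extended classifier consumes the original RGB channels together
with the nine feature activation maps as a single 12-channel image.  The
only architectural change this requires of a standard CNN is the depth of
its first convolution layer (3 -> 12 input channels); all other layers are
untouched.  This module provides:

* channel stacking (RGB scaled to [0, 1] + the 9 feature maps),
* the resize to the 224x224 network input resolution (cubic, per channel),
* expansion of a pretrained first-layer kernel bank from 3 to 12 input
  channels, either function-preserving (zero init) or mean-replicated,
* output-probability ensembling across the models of a cross-validation.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .primitives import InvalidInputError, as_color_image

__all__ = [
    "MODEL_INPUT_SIZE",
    "stack_channels",
    "to_model_input",
    "expand_input_kernels",
    "ensemble_scores",
]

MODEL_INPUT_SIZE = 224


def stack_channels(img: np.ndarray, feats: np.ndarray) -> np.ndarray:
    """Concatenate RGB (scaled to [0, 1]) with the 9 feature maps.

    Returns an (H, W, 12) float array: channels 0-2 are r, g, b / 255,
    channels 3-11 are the feature maps F1..F9 unchanged.
    """
    img = as_color_image(img)
    feats = np.asarray(feats, dtype=np.float64)
    if feats.ndim != 3 or feats.shape[2] != 9:
        raise InvalidInputError(f"expected (H, W, 9) feature stack, got {feats.shape}")
    if img.shape[:2] != feats.shape[:2]:
        raise InvalidInputError(
            f"image {img.shape[:2]} and feature stack {feats.shape[:2]} shapes differ"
        )
    return np.concatenate([img.astype(np.float64) / 255.0, feats], axis=2)


def to_model_input(stacked: np.ndarray, size: int = MODEL_INPUT_SIZE) -> np.ndarray:
    """Resize a stacked (H, W, C) tensor to (size, size, C) with cubic interpolation.

    Each channel is resized independently; cubic overshoot is clipped back
    to [0, 1].
    """
    stacked = np.asarray(stacked, dtype=np.float64)
    if stacked.ndim != 3:
        raise InvalidInputError(f"expected (H, W, C) tensor, got shape {stacked.shape}")
    out = resize(
        stacked,
        (size, size, stacked.shape[2]),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def expand_input_kernels(
    bank: np.ndarray, extra: int = 9, init_mode: str = "zero"
) -> np.ndarray:
    """Expand a first-layer kernel bank from 3 to 3 + ``extra`` input channels.

    Parameters
    ----------
    bank : (k, k, 3, C_out) array
        First convolution layer weights of an RGB network.
    extra : int
        Number of input channels to append (9 for the feature stack).
    init_mode : {"zero", "mean-replicate"}
        ``zero`` leaves the network function-preserving on inputs whose new
        channels are zero; ``mean-replicate`` initializes each new slice to
        the mean of the RGB slices (a transfer-learning warm start).

    The original 3 input slices are preserved bit-exactly.
    """
    bank = np.asarray(bank)
    if bank.ndim != 4 or bank.shape[2] != 3:
        raise InvalidInputError(
            f"expected (k, k, 3, C_out) kernel bank, got shape {bank.shape}"
        )
    if init_mode == "zero":
        new = np.zeros(bank.shape[:2] + (extra, bank.shape[3]), dtype=bank.dtype)
    elif init_mode == "mean-replicate":
        mean = bank.mean(axis=2, keepdims=True)
        new = np.repeat(mean, extra, axis=2).astype(bank.dtype)
    else:
        raise InvalidInputError(f"unknown init_mode: {init_mode!r}")
    return np.concatenate([bank, new], axis=2)


def ensemble_scores(scores) -> float:
    """Average the output probabilities of an ensemble of models."""
    arr = np.asarray(list(scores), dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("ensemble requires at least one model score")
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidInputError("model scores must lie in [0, 1]")
    return float(arr.mean())
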
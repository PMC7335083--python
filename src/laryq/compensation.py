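"""RGB <-> YCbCr conversion and histogram-shift brightness normalization.

All conversions use the full-range ITU-R BT.601 matrix so that the luma
plane Y spans [0, 255] and achromatic pixels map to Cb = Cr = 128.
Brightness compensation shifts every Y value by ``target - mean(Y)`` and
leaves the chroma planes untouched, so hue features downstream are
invariant to the correction.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InvalidInputError

log = logging.getLogger(__name__)

DEFAULT_TARGET_LUMA = 125.0

# Full-range BT.601 forward matrix (rows: Y, Cb, Cr).
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_INV = np.linalg.inv(_FWD)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(
            f"expected an (rows, cols, 3) RGB image, got shape {image.shape}"
        )
    return image


def rgb_to_ycbcr(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to float YCbCr planes stacked as (..., 3).

    Y is in [0, 255]; Cb and Cr are centred on 128.  The result is float64
    so that a round trip through :func:`ycbcr_to_rgb` loses at most one
    gray level to final rounding.
    """
    image = _check_rgb(image).astype(np.float64)
    ycc = image @ _FWD.T
    ycc[..., 1] += 128.0
    ycc[..., 2] += 128.0
    return ycc


def ycbcr_to_rgb(ycbcr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycbcr`; returns a clipped uint8 RGB image."""
    ycc = _check_rgb(ycbcr).astype(np.float64).copy()
    ycc[..., 1] -= 128.0
    ycc[..., 2] -= 128.0
    rgb = ycc @ _INV.T
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def luma(image: np.ndarray) -> np.ndarray:
    """BT.601 luma plane of an RGB image, float64 in [0, 255]."""
    return rgb_to_ycbcr(image)[..., 0]


def histogram_shift(
    image: np.ndarray, target: float = DEFAULT_TARGET_LUMA
) -> np.ndarray:
    """Shift the luma histogram so the mean Y equals ``target``.

    Every Y value gets the same additive offset ``target - mean(Y)``;
    values pushed outside [0, 255] are clipped and the clipped fraction is
    logged.  Chroma planes pass through unchanged.  When nothing clips the
    post-shift mean luma equals ``target`` to within rounding (0.5 gray
    level).
    """
    ycc = rgb_to_ycbcr(image)
    offset = target - float(ycc[..., 0].mean())
    shifted = ycc[..., 0] + offset
    n_clip = int(np.count_nonzero((shifted < 0) | (shifted > 255)))
    if n_clip:
        log.warning(
            "histogram_shift clipped %d/%d pixels (offset %.2f)",
            n_clip,
            shifted.size,
            offset,
        )
    ycc[..., 0] = np.clip(shifted, 0.0, 255.0)
    return ycbcr_to_rgb(ycc)
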
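"""Frame screening: non-throat / blur rejection and sharpest-frame selection.

Four autofocus scores are available: gray-level variance, sum-modulus-
difference (SMD, horizontal + vertical first differences), Tenengrad-style
Sobel gradient magnitude, and the energy of the discrete Laplacian.  All
are zero on constant frames and strictly decrease under Gaussian blur of a
textured frame.  Screening first drops frames whose red chromatic fraction
falls below a threshold (non-throat frames), then drops frames whose
variance is strictly below the mean variance of the survivors; the mean is
computed once, not iterated.

Gray conversion for every score is the BT.601 luma plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .compensation import luma
from .errors import InvalidInputError

log = logging.getLogger(__name__)

RED_THRESHOLD = 0.4

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T
_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)

SHARPNESS_METHODS = ("variance", "smd", "sobel", "laplacian")


def _as_gray(gray: np.ndarray, min_shape: tuple[int, int] = (1, 1)) -> np.ndarray:
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise InvalidInputError(f"expected a 2-D gray image, got shape {gray.shape}")
    if gray.shape[0] < min_shape[0] or gray.shape[1] < min_shape[1]:
        raise InvalidInputError(
            f"image {gray.shape} smaller than required {min_shape}"
        )
    return gray


def red_fraction(image: np.ndarray) -> float:
    """Mean over pixels of R / (R + G + B); 0/0 pixels count as 0."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3 or image[..., 0].size == 0:
        raise InvalidInputError("expected a non-empty RGB image")
    total = image.sum(axis=2)
    frac = np.divide(
        image[..., 0], total, out=np.zeros_like(total), where=total > 0
    )
    return float(frac.mean())


def variance_score(gray: np.ndarray) -> float:
    """Population variance of the gray levels."""
    gray = _as_gray(gray)
    if gray.size == 0:
        raise InvalidInputError("empty image")
    return float(gray.var())


def smd_score(gray: np.ndarray) -> float:
    """Sum of |first differences|, horizontal (SMD_x) plus vertical (SMD_y)."""
    gray = _as_gray(gray, (2, 2))
    smd_x = np.abs(np.diff(gray, axis=1)).sum()
    smd_y = np.abs(np.diff(gray, axis=0)).sum()
    return float(smd_x + smd_y)


def sobel_score(gray: np.ndarray) -> float:
    """Sum of Sobel gradient magnitudes over interior pixels (no padding)."""
    gray = _as_gray(gray, (3, 3))
    gx = convolve2d(gray, _SOBEL_X, mode="valid")
    gy = convolve2d(gray, _SOBEL_Y, mode="valid")
    return float(np.sqrt(gx**2 + gy**2).sum())


def laplacian_score(gray: np.ndarray) -> float:
    """Sum of squared discrete-Laplacian responses over interior pixels."""
    gray = _as_gray(gray, (3, 3))
    resp = convolve2d(gray, _LAPLACIAN, mode="valid")
    return float((resp**2).sum())


_SCORE_FUNCS = {
    "variance": variance_score,
    "smd": smd_score,
    "sobel": sobel_score,
    "laplacian": laplacian_score,
}


@dataclass
class SharpnessReport:
    """Per-frame sharpness scores and screening flags for a frame stack."""

    variance: list[float] = field(default_factory=list)
    smd: list[float] = field(default_factory=list)
    sobel: list[float] = field(default_factory=list)
    laplacian: list[float] = field(default_factory=list)
    red_fraction: list[float] = field(default_factory=list)
    passed_red: list[bool] = field(default_factory=list)
    passed_variance: list[bool] = field(default_factory=list)

    @property
    def surviving(self) -> list[int]:
        return [
            i
            for i, (r, v) in enumerate(zip(self.passed_red, self.passed_variance))
            if r and v
        ]


def sharpness_report(
    stack: list[np.ndarray], red_threshold: float = RED_THRESHOLD
) -> SharpnessReport:
    """Score every frame and mark the red / variance screening decisions."""
    if len(stack) == 0:
        raise InvalidInputError("empty frame stack")
    report = SharpnessReport()
    grays = []
    for frame in stack:
        gray = luma(frame)
        grays.append(gray)
        report.red_fraction.append(red_fraction(frame))
        report.variance.append(variance_score(gray))
        report.smd.append(smd_score(gray))
        report.sobel.append(sobel_score(gray))
        report.laplacian.append(laplacian_score(gray))
    report.passed_red = [r >= red_threshold for r in report.red_fraction]
    reds = [i for i, ok in enumerate(report.passed_red) if ok]
    if reds:
        mean_var = float(np.mean([report.variance[i] for i in reds]))
    else:
        mean_var = 0.0
    report.passed_variance = [
        ok and report.variance[i] >= mean_var
        for i, ok in enumerate(report.passed_red)
    ]
    return report


def screen(
    stack: list[np.ndarray], red_threshold: float = RED_THRESHOLD
) -> list[int]:
    """Indices of frames surviving the red filter then the variance filter.

    Frames with red fraction below ``red_threshold`` are removed; among
    the rest, frames with variance strictly below the survivors' mean
    variance are removed.  An empty result logs a warning instead of
    raising.
    """
    report = sharpness_report(stack, red_threshold)
    surviving = report.surviving
    if not surviving:
        log.warning("screen: all %d frames were filtered out", len(stack))
    return surviving


def select_sharpest(
    stack: list[np.ndarray],
    indices: list[int] | None = None,
    method: str = "smd",
) -> int:
    """Index of the sharpest frame among ``indices`` under ``method``.

    Ties are broken in favour of the lowest index.
    """
    if method not in _SCORE_FUNCS:
        raise InvalidInputError(
            f"unknown method {method!r}; choose from {SHARPNESS_METHODS}"
        )
    if indices is None:
        indices = list(range(len(stack)))
    if len(indices) == 0:
        raise InvalidInputError("no candidate frames")
    score = _SCORE_FUNCS[method]
    best_i, best_s = None, -np.inf
    for i in indices:
        s = score(luma(stack[i]))
        if s > best_s:
            best_i, best_s = i, s
    return int(best_i)
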
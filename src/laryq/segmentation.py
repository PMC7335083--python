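"""Automatic segmentation of glottis, arytenoid cartilage and vocal cords.

Stages:

* glottis — global gray statistics give a lower-bound threshold TH = mu -
  sigma; dark pixels are labelled and filtered by area / centroid zone /
  bounding-box aspect (the glottis is a dark, centrally located,
  not-too-wide region), keeping the largest survivor.
* arytenoid — bright pixels (> mu + k sigma) are eroded and labelled; the
  largest component located in the upper image band with a wide-enough
  bounding box seeds an active contour initialized on its dilated boundary
  and contracted onto the gradient edges.
* vocal cords — the glottis is dilated and transected through its centroid
  row; scanning the smoothed gray profile outward on each side locates the
  brightness valley separating true and false vocal cords.  A contour is
  initialized spanning glottis edge to valley and evolved with the
  entropy-difference adaptive stopping rule.

All masks are boolean arrays indexed (row, col); outputs are pairwise
disjoint (the glottis is subtracted from the cord masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, uniform_filter1d
from scipy.signal import find_peaks
from skimage import measure

from .compensation import luma
from .errors import InvalidInputError, RegionNotFoundError
from .snake import (
    MAX_ITER_DEFAULT,
    MIN_ITER_DEFAULT,
    AdaptiveResult,
    Snake,
    adaptive_evolve,
    evolve,
    external_energy_field,
)

_SE3 = np.ones((3, 3), dtype=bool)


@dataclass
class RegionSet:
    """Binary masks of the four analyzed structures (same shape, disjoint)."""

    glottis: np.ndarray
    left_vc: np.ndarray
    right_vc: np.ndarray
    arytenoid: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "glottis": self.glottis,
            "left_vc": self.left_vc,
            "right_vc": self.right_vc,
            "arytenoid": self.arytenoid,
        }


@dataclass
class StructureRules:
    """Component filters: minimum area, centroid zone, bbox aspect bounds.

    ``centroid_zone`` is (row_min, row_max, col_min, col_max) in normalized
    [0, 1] image coordinates; aspect is bbox width / bbox height.
    """

    min_area_frac: float = 0.005
    centroid_zone: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)
    aspect_min: float = 0.01
    aspect_max: float = 100.0

    def __post_init__(self):
        if not 0 < self.aspect_min < self.aspect_max:
            raise InvalidInputError("need 0 < aspect_min < aspect_max")
        r0, r1, c0, c1 = self.centroid_zone
        if not (0 <= r0 < r1 <= 1 and 0 <= c0 < c1 <= 1):
            raise InvalidInputError("centroid_zone must be within [0,1]^2")


# defaults calibrated on phantoms; all overridable
GLOTTIS_RULES = StructureRules(
    min_area_frac=0.005,
    centroid_zone=(0.25, 0.75, 0.25, 0.75),
    aspect_min=0.01,
    aspect_max=2.0,
)
ARYTENOID_RULES = StructureRules(
    min_area_frac=0.005,
    centroid_zone=(0.0, 0.40, 0.05, 0.95),
    aspect_min=1.0,
    aspect_max=100.0,
)


def glottis_threshold(gray: np.ndarray) -> float:
    """Lower-bound binarization threshold TH = mu - sigma, clamped to [0,255]."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size == 0:
        raise InvalidInputError("empty image")
    return float(np.clip(gray.mean() - gray.std(), 0.0, 255.0))


def binarize_dark(gray: np.ndarray, threshold: float) -> np.ndarray:
    """Pixels strictly below the threshold."""
    return np.asarray(gray, dtype=np.float64) < threshold


def binarize_bright(gray: np.ndarray, k: float = 0.5) -> np.ndarray:
    """Pixels strictly above mu + k sigma."""
    gray = np.asarray(gray, dtype=np.float64)
    return gray > gray.mean() + k * gray.std()


@dataclass
class Component:
    id: int
    area: int
    centroid: tuple[float, float]
    bbox_aspect: float
    mask: np.ndarray = field(repr=False)


def label_components(mask: np.ndarray) -> list[Component]:
    """8-connected components ordered by descending area."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        height = max(r1 - r0, 1)
        comps.append(
            Component(
                id=region.label,
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                bbox_aspect=(c1 - c0) / height,
                mask=labels == region.label,
            )
        )
    comps.sort(key=lambda c: (-c.area, c.id))
    return comps


def apply_structure_rules(
    components: list[Component],
    rules: StructureRules,
    image_dims: tuple[int, int],
) -> Component | None:
    """Largest component passing area / centroid / aspect filters, else None."""
    rows, cols = image_dims
    min_area = rules.min_area_frac * rows * cols
    r0, r1, c0, c1 = rules.centroid_zone
    survivors = [
        c
        for c in components
        if c.area >= min_area
        and r0 * rows <= c.centroid[0] <= r1 * rows
        and c0 * cols <= c.centroid[1] <= c1 * cols
        and rules.aspect_min <= c.bbox_aspect <= rules.aspect_max
    ]
    if not survivors:
        return None
    return max(survivors, key=lambda c: c.area)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B| / (|A|+|B|); 1.0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError("mask dimensions differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _mask_contour(mask: np.ndarray, spacing: float = 3.0) -> np.ndarray:
    """Sub-sampled boundary polygon of a mask, (N, 2) (row, col) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise InvalidInputError("mask has no boundary contour")
    contour = max(contours, key=len)
    step = max(int(round(spacing)), 1)
    pts = contour[:-1:step]
    if len(pts) < 4:
        pts = contour[:-1]
    if len(pts) < 4:
        raise InvalidInputError("contour too short for a snake")
    return pts


def _edge_samples(a: float, b: float, spacing: float) -> np.ndarray:
    """Midpoint samples of [a, b): mirror-symmetric as a coordinate set."""
    n = max(int(round(abs(b - a) / spacing)), 1)
    k = np.arange(n)
    return a + (k + 0.5) * (b - a) / n


def _rect_polygon(
    r0: float, r1: float, c0: float, c1: float, spacing: float = 3.0
) -> np.ndarray:
    """Closed rectangle polygon sampled every ~spacing pixels, (row, col).

    Edges are sampled at bin midpoints so a horizontally mirrored rectangle
    yields exactly the mirrored point set.
    """
    top = [(r0, c) for c in _edge_samples(c0, c1, spacing)]
    right = [(r, c1) for r in _edge_samples(r0, r1, spacing)]
    bottom = [(r1, c) for c in _edge_samples(c1, c0, spacing)]
    left = [(r, c0) for r in _edge_samples(r1, r0, spacing)]
    return np.array(top + right + bottom + left, dtype=np.float64)


def segment_glottis(
    image: np.ndarray, rules: StructureRules = GLOTTIS_RULES
) -> np.ndarray:
    """Dark-region glottis mask from a brightness-compensated RGB image."""
    gray = luma(image)
    th = glottis_threshold(gray)
    comps = label_components(binarize_dark(gray, th))
    chosen = apply_structure_rules(comps, rules, gray.shape)
    if chosen is None:
        raise RegionNotFoundError("glottis")
    return chosen.mask


def segment_arytenoid(
    image: np.ndarray,
    rules: StructureRules = ARYTENOID_RULES,
    bright_k: float = 0.5,
    snake_iters: int = 30,
    alpha: float = 0.05,
    beta: float = 0.1,
    pressure: float = -2.0,
    return_candidate: bool = False,
):
    """Bright-region arytenoid mask refined by a contracting active contour.

    The eroded bright-pixel candidate passing the upper-band structure rules
    seeds a snake on its dilated boundary; deflation pressure pulls the
    contour onto the gradient edges of the block.  Returns the filled
    contour polygon (and the pre-snake candidate when requested).
    """
    gray = luma(image)
    bright = binarize_bright(gray, bright_k)
    eroded = binary_erosion(bright, _SE3, iterations=1)
    comps = label_components(eroded)
    chosen = apply_structure_rules(comps, rules, gray.shape)
    if chosen is None:
        raise RegionNotFoundError("arytenoid")
    init_mask = binary_dilation(chosen.mask, _SE3, iterations=3)
    contour = _mask_contour(init_mask)
    field_ = external_energy_field(gray)
    snk = evolve(
        Snake(contour, alpha=alpha, beta=beta, search_radius=1),
        field_,
        snake_iters,
        pressure=pressure,
    )
    refined = snk.enclosed_mask(gray.shape)
    if refined.sum() == 0:
        raise RegionNotFoundError("arytenoid", "contour collapsed")
    if return_candidate:
        return refined, chosen.mask
    return refined


def _find_valley(
    profile: np.ndarray, start: int, direction: int, prominence: float = 25.0
) -> int:
    """First prominent intensity minimum beyond the brightness peak.

    ``direction`` is +1 (rightward) or -1 (leftward).  The brightness peak
    (the vocal cord) is the maximum on the scan side nearest to ``start``;
    the valley is the closest local minimum beyond it whose prominence
    exceeds ``prominence`` gray levels, which rejects shallow speckle dips
    inside the cord.  Raises if no such minimum exists.
    """
    n = len(profile)
    order = np.arange(start, -1, -1) if direction < 0 else np.arange(start, n)
    if order.size == 0:
        raise InvalidInputError("empty scan range")
    peak = int(order[np.argmax(profile[order])])
    minima, _ = find_peaks(-profile, prominence=prominence)
    beyond = minima[(minima - peak) * direction > 0]
    if beyond.size == 0:
        raise InvalidInputError("no valley within scan range")
    return int(beyond[np.argmin(np.abs(beyond - peak))])


def segment_vocal_cords(
    image: np.ndarray,
    glottis_mask: np.ndarray,
    min_iter: int = MIN_ITER_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
    alpha: float = 0.05,
    beta: float = 0.1,
    pressure: float = -8.0,
    row_margin: int = 14,
    return_info: bool = False,
):
    """Segment both vocal cords; returns (left_mask, right_mask).

    The glottis is dilated (3x3, 2 passes) and transected along its
    centroid row; the gray profile on that row is smoothed (moving average,
    width 3) and scanned outward on each side for the valley between true
    and false cord.  Per side a contour is initialized from the dilated
    glottis edge out to the valley (rows padded by ``row_margin``) and run
    through entropy-difference adaptive evolution.  With ``return_info`` the
    per-side :class:`AdaptiveResult` objects are returned as well.
    """
    glottis_mask = np.asarray(glottis_mask, dtype=bool)
    if glottis_mask.sum() == 0:
        raise InvalidInputError("empty glottis mask")
    gray = luma(image)
    rows, cols = gray.shape
    dilated = binary_dilation(glottis_mask, _SE3, iterations=2)

    g_rows, _ = np.nonzero(glottis_mask)
    centroid_row = int(round(g_rows.mean()))
    row_cols = np.nonzero(dilated[centroid_row])[0]
    if row_cols.size == 0:
        raise InvalidInputError("dilated glottis does not cover centroid row")
    edge_left, edge_right = int(row_cols.min()), int(row_cols.max())

    profile = uniform_filter1d(gray[centroid_row], size=3, mode="nearest")
    field_ = external_energy_field(gray)
    r0 = max(int(g_rows.min()) - row_margin, 0)
    r1 = min(int(g_rows.max()) + row_margin, rows - 1)

    results: dict[str, tuple[np.ndarray, AdaptiveResult]] = {}
    for side, edge, direction in (
        ("left", edge_left, -1),
        ("right", edge_right, +1),
    ):
        name = f"{side}_vc"
        try:
            valley = _find_valley(profile, edge, direction)
        except InvalidInputError as exc:
            raise RegionNotFoundError(name, str(exc)) from exc
        # start 2 px inside the valley so the outer contour edge contracts
        # onto the cord-side wall of the valley, not the far wall
        outer = valley - 2 * direction
        c0, c1 = sorted((float(edge), float(outer)))
        init = _rect_polygon(float(r0), float(r1), c0, c1)
        result = adaptive_evolve(
            Snake(init, alpha=alpha, beta=beta, search_radius=1),
            field_,
            gray,
            min_iter=min_iter,
            max_iter=max_iter,
            pressure=pressure,
            resample_spacing=3.0,
            update="parallel",
        )
        mask = result.snake.enclosed_mask(gray.shape)
        mask &= ~glottis_mask  # enforce disjointness
        if mask.sum() == 0:
            raise RegionNotFoundError(name, "contour collapsed")
        results[side] = (mask, result)

    left_mask, left_res = results["left"]
    right_mask, right_res = results["right"]
    # assign laterality by mask centroid column (left = smaller column)
    if np.nonzero(left_mask)[1].mean() > np.nonzero(right_mask)[1].mean():
        left_mask, right_mask = right_mask, left_mask
        left_res, right_res = right_res, left_res
    if return_info:
        return (left_mask, right_mask), (left_res, right_res)
    return left_mask, right_mask


def segment_regions(
    image: np.ndarray,
    glottis_rules: StructureRules = GLOTTIS_RULES,
    arytenoid_rules: StructureRules = ARYTENOID_RULES,
) -> RegionSet:
    """Full RegionSet for a compensated frame (glottis, cords, arytenoid)."""
    glottis = segment_glottis(image, glottis_rules)
    arytenoid = segment_arytenoid(image, arytenoid_rules)
    left_vc, right_vc = segment_vocal_cords(image, glottis)
    arytenoid &= ~(glottis | left_vc | right_vc)
    return RegionSet(
        glottis=glottis, left_vc=left_vc, right_vc=right_vc, arytenoid=arytenoid
    )
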
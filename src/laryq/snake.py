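"""Active contour (snake) model with greedy energy minimization.

The contour is a closed polygon of sub-pixel (row, col) control points.
Internal energy is the discretized elasticity/curvature functional

    E_int = 1/2 * sum_i ( alpha * |v_s(i)|^2 + beta * |v_ss(i)|^2 )

with cyclic first differences ``v_s(i) = v[i+1] - v[i]`` and central second
differences ``v_ss(i) = v[i+1] - 2 v[i] + v[i-1]``.  External energy is the
negated squared gradient magnitude of the gray image, so edges are energy
wells.  Evolution is a deterministic greedy scheme: each iteration visits
every control point in order and moves it to the integer-offset candidate
within the search window that strictly lowers its local contribution to the
total energy; ties keep the current position.  With zero pressure the total
energy is therefore non-increasing per iteration.

An optional pressure (balloon) term biases motion along the outward normal
(positive inflates, negative deflates); it enters the greedy objective only
and is excluded from :func:`total_energy`.

Adaptive stopping: the Shannon entropy of the gray levels enclosed by the
contour is tracked per iteration, and the iteration count in a configured
window with the smallest successive entropy difference is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import measure
from skimage.draw import polygon2mask

from .errors import DegenerateContourError, InvalidInputError

MIN_ITER_DEFAULT = 13
MAX_ITER_DEFAULT = 41


@dataclass
class Snake:
    """Closed contour with elasticity weight alpha and curvature weight beta.

    ``points`` is an (N, 2) float array of (row, col) positions; the
    successor of the last point is the first.
    """

    points: np.ndarray
    alpha: float = 1.0
    beta: float = 0.5
    search_radius: int = 1

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("points must be an (N, 2) array")
        if len(self.points) < 4:
            raise InvalidInputError("a snake needs at least 4 points")
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("alpha and beta must be non-negative")
        if self.search_radius < 1:
            raise InvalidInputError("search_radius must be >= 1")

    def enclosed_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of pixels inside the contour polygon."""
        return polygon2mask(shape, self.points)

    def enclosed_area(self) -> float:
        """Polygon area by the shoelace formula (always >= 0)."""
        r = self.points[:, 0]
        c = self.points[:, 1]
        return float(
            abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2.0
        )


@dataclass
class EnergyField:
    """External per-pixel energy: edge map plus optional constraint map."""

    external: np.ndarray
    con: np.ndarray | None = None

    def __post_init__(self):
        self.external = np.asarray(self.external, dtype=np.float64)
        if self.external.ndim != 2:
            raise InvalidInputError("external field must be 2-D")

    def total(self) -> np.ndarray:
        if self.con is None:
            return self.external
        return self.external + np.asarray(self.con, dtype=np.float64)


def internal_energy(snake: Snake) -> float:
    """1/2 * sum(alpha |v_s|^2 + beta |v_ss|^2) over cyclic control points."""
    p = snake.points
    v_s = np.roll(p, -1, axis=0) - p
    v_ss = np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)
    return float(
        0.5
        * (
            snake.alpha * (v_s**2).sum()
            + snake.beta * (v_ss**2).sum()
        )
    )


def external_energy_field(
    gray: np.ndarray, smooth_sigma: float = 1.0
) -> EnergyField:
    """Edge-attraction field: -(|grad I|^2) with central differences.

    The image is optionally Gaussian-smoothed first (``smooth_sigma=0``
    disables it) to widen the capture range of the gradient wells; border
    pixels use one-sided differences.  Values are <= 0 everywhere.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise InvalidInputError("gray image must be 2-D and at least 3x3")
    if smooth_sigma > 0:
        gray = gaussian_filter(gray, smooth_sigma)
    gr, gc = np.gradient(gray)
    return EnergyField(external=-(gr**2 + gc**2))


def _sample(field2d: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear sample of a 2-D map at fractional (row, col) points."""
    return map_coordinates(
        field2d, [points[:, 0], points[:, 1]], order=1, mode="nearest"
    )


def total_energy(snake: Snake, field: EnergyField) -> float:
    """Internal energy plus the external field sampled at the points."""
    return internal_energy(snake) + float(_sample(field.total(), snake.points).sum())


def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals per point, robust to polygon orientation."""
    tang = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    # rotate tangent by 90 degrees; sign fixed via the signed area
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    r, c = points[:, 0], points[:, 1]
    signed_area = (np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2.0
    if signed_area > 0:
        normals = -normals
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def _local_energies(
    p: np.ndarray,
    i: int,
    offsets: np.ndarray,
    ext: np.ndarray,
    alpha: float,
    beta: float,
    pressure: float,
    normals: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local objective of every candidate position for control point i."""
    n = len(p)
    rows, cols = ext.shape
    prev2, prev1 = p[(i - 2) % n], p[(i - 1) % n]
    nxt1, nxt2 = p[(i + 1) % n], p[(i + 2) % n]
    cand = p[i] + offsets
    np.clip(cand[:, 0], 0, rows - 1, out=cand[:, 0])
    np.clip(cand[:, 1], 0, cols - 1, out=cand[:, 1])
    e = 0.5 * alpha * (
        ((cand - prev1) ** 2).sum(axis=1) + ((nxt1 - cand) ** 2).sum(axis=1)
    )
    if beta:
        e += 0.5 * beta * (
            ((cand - 2 * prev1 + prev2) ** 2).sum(axis=1)
            + ((nxt1 - 2 * cand + prev1) ** 2).sum(axis=1)
            + ((nxt2 - 2 * nxt1 + cand) ** 2).sum(axis=1)
        )
    e += _sample(ext, cand)
    if pressure != 0.0 and normals is not None:
        e -= pressure * (cand - p[i]) @ normals[i]
    return e, cand


def evolve(
    snake: Snake,
    field: EnergyField,
    n_iter: int,
    pressure: float = 0.0,
    update: str = "serial",
) -> Snake:
    """Greedy evolution for ``n_iter`` iterations; returns a new Snake.

    ``pressure`` > 0 inflates (biases candidates along the outward normal),
    < 0 deflates; 0 gives pure energy descent, for which the total energy is
    non-increasing per iteration in serial mode.

    ``update="serial"`` visits points in order, each seeing its neighbours'
    already-updated positions; candidate ties keep the current position,
    else the lowest row-major candidate wins.  ``update="parallel"``
    evaluates all points against the current configuration and applies the
    moves simultaneously with a left/right-symmetric tie rule (energy, then
    row offset, then |column offset|; an exact +-dc tie keeps the point),
    which makes the evolution equivariant under horizontal mirroring.
    """
    if n_iter < 1:
        raise InvalidInputError("n_iter must be >= 1")
    if update not in ("serial", "parallel"):
        raise InvalidInputError("update must be 'serial' or 'parallel'")
    ext = field.total()
    p = snake.points.copy()
    n = len(p)
    r = snake.search_radius
    offsets = np.array(
        [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)],
        dtype=np.float64,
    )
    cur_idx = r * (2 * r + 1) + r  # index of the (0, 0) offset
    # symmetric preference order: (dr, |dc|), used by the parallel rule
    sym_rank = np.lexsort((np.abs(offsets[:, 1]), offsets[:, 0]))
    alpha, beta = snake.alpha, snake.beta

    for _ in range(n_iter):
        normals = _outward_normals(p) if pressure != 0.0 else None
        if update == "serial":
            for i in range(n):
                e, cand = _local_energies(
                    p, i, offsets, ext, alpha, beta, pressure, normals
                )
                best = int(np.argmin(e))  # first (row-major) minimum
                if e[best] < e[cur_idx]:
                    p[i] = cand[best]
        else:
            new_p = p.copy()
            for i in range(n):
                e, cand = _local_energies(
                    p, i, offsets, ext, alpha, beta, pressure, normals
                )
                e_min = e.min()
                if not e_min < e[cur_idx]:
                    continue
                winners = sym_rank[e[sym_rank] == e_min]
                best = int(winners[0])
                dr0, dc0 = offsets[best]
                # +-dc tie at identical rank: keep the point (symmetry)
                mirror = np.nonzero(
                    (offsets[winners, 0] == dr0)
                    & (offsets[winners, 1] == -dc0)
                )[0]
                if dc0 != 0 and mirror.size:
                    continue
                new_p[i] = cand[best]
            p = new_p
    return replace(snake, points=p)


def resample_polygon(
    points: np.ndarray, spacing: float = 3.0, canonical_start: bool = False
) -> np.ndarray:
    """Redistribute points uniformly along the closed polyline.

    Keeps the total perimeter and shape, spacing control points every
    ``spacing`` pixels (at least 8 points).  Used between adaptive
    iterations to stop points bunching along edges.  With
    ``canonical_start`` the walk starts from a geometrically canonical
    vertex (topmost, then nearest the centroid column), which makes the
    resampled point set invariant to traversal direction and start index —
    needed for mirror equivariance.
    """
    pts = np.asarray(points, dtype=np.float64)
    if canonical_start:
        top = pts[:, 0] == pts[:, 0].min()
        idx_top = np.nonzero(top)[0]
        dist = np.abs(pts[idx_top, 1] - pts[:, 1].mean())
        start = int(idx_top[np.argmin(dist)])
        pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg_len = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = seg_len.sum()
    if perimeter == 0:
        return pts.copy()
    n_new = max(int(round(perimeter / spacing)), 8)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0.0, perimeter, n_new, endpoint=False)
    out = np.empty((n_new, 2))
    out[:, 0] = np.interp(targets, cum, closed[:, 0])
    out[:, 1] = np.interp(targets, cum, closed[:, 1])
    return out


def region_entropy(gray: np.ndarray, mask: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray histogram under the mask."""
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise InvalidInputError("gray and mask dimensions differ")
    vals = gray[mask]
    if vals.size == 0:
        raise InvalidInputError("empty mask")
    hist, _ = np.histogram(vals, bins=256, range=(0, 256))
    p = hist[hist > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


@dataclass
class AdaptiveResult:
    snake: Snake
    n_star: int
    entropy_diffs: list[float] = field(default_factory=list)
    entropies: list[float] = field(default_factory=list)


def adaptive_evolve(
    snake: Snake,
    field: EnergyField,
    gray: np.ndarray,
    min_iter: int = MIN_ITER_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
    pressure: float = 0.0,
    resample_spacing: float | None = None,
    update: str = "serial",
) -> AdaptiveResult:
    """Evolve one iteration at a time and stop by minimum entropy difference.

    After each iteration i the entropy H_i of the enclosed region is
    recorded; n_star is the i in [min_iter, max_iter] minimizing
    |H_i - H_{i-1}| (ties -> smallest i) and the returned snake is the state
    after iteration n_star.  With ``resample_spacing`` the control points
    are redistributed uniformly along the contour after every iteration.
    """
    if min_iter < 2:
        raise InvalidInputError("min_iter must be >= 2")
    if max_iter < min_iter:
        raise InvalidInputError("max_iter must be >= min_iter")
    gray = np.asarray(gray, dtype=np.float64)
    shape = gray.shape

    entropies: list[float] = []
    snapshots: list[np.ndarray] = []
    cur = snake
    for i in range(1, max_iter + 1):
        cur = evolve(cur, field, 1, pressure=pressure, update=update)
        if resample_spacing is not None:
            # reproject through the rasterized region: keeps the polygon
            # simple (no self-intersection) and the points evenly spaced
            region = cur.enclosed_mask(shape)
            contours = (
                measure.find_contours(region.astype(float), 0.5)
                if region.any()
                else []
            )
            if contours:
                boundary = max(contours, key=len)[:-1]
                pts = resample_polygon(
                    boundary,
                    resample_spacing,
                    canonical_start=(update == "parallel"),
                )
                if len(pts) >= 4:
                    cur = replace(cur, points=pts)
        mask = cur.enclosed_mask(shape)
        if mask.sum() == 0:
            if i < min_iter:
                raise DegenerateContourError(
                    f"contour collapsed at iteration {i} (< min_iter {min_iter})"
                )
            entropies.append(0.0)
        else:
            entropies.append(region_entropy(gray, mask))
        snapshots.append(cur.points.copy())

    # entropies[i-1] is H_i; diffs[i-2] is |H_i - H_{i-1}| for i >= 2
    diffs = [
        abs(entropies[i - 1] - entropies[i - 2])
        for i in range(2, max_iter + 1)
    ]
    window = [(abs(entropies[i - 1] - entropies[i - 2]), i)
              for i in range(max(min_iter, 2), max_iter + 1)]
    _, n_star = min(window, key=lambda t: (t[0], t[1]))
    best = replace(snake, points=snapshots[n_star - 1])
    return AdaptiveResult(
        snake=best, n_star=n_star, entropy_diffs=diffs, entropies=entropies
    )
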
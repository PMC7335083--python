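"""Synthetic laryngeal phantoms with known ground truth.

A phantom frame contains a dark inverted-triangle glottis near the image
centre, two bright columnar vocal cords flanking it, darker valley strips
separating true from false cords, a bright rectangular arytenoid block in
the upper image band, and a mucosa-coloured background.  Structures carry
seeded Gaussian speckle so texture statistics are non-degenerate; the
reflux (LPR) effect reddens the cords, shifts the arytenoid chroma and
scales the cord speckle contrast, all applied before noise.

Also provided: frame stacks with blur / motion / non-throat distractors for
the screening stage, and tabular feature cohorts for the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .compensation import rgb_to_ycbcr, ycbcr_to_rgb
from .errors import InvalidParameterError
from .features import FEATURE_NAMES, SELECTED_FEATURES
from .segmentation import RegionSet

LPR_LABEL = "LPR"
NON_LPR_LABEL = "non-LPR"

SEVERITY_BINS = {"primary": (13, 20), "intermediate": (21, 30), "severe": (31, 45)}


@dataclass
class LprEffect:
    """Hue/texture shifts applied to an LPR phantom (before noise)."""

    vc_red_shift: float = 25.0
    aryt_cb_shift: float = -12.0
    aryt_cr_shift: float = 12.0
    vc_contrast_gain: float = 1.6


@dataclass
class PhantomParams:
    """Geometry, shading and randomness of a synthetic laryngeal frame."""

    image_size: tuple[int, int] = (256, 256)
    # (row, col) vertices: top-left, top-right, apex (pointing down)
    glottis_vertices: tuple[tuple[int, int], ...] = (
        (100, 116),
        (100, 140),
        (190, 128),
    )
    vc_rows: tuple[int, int] = (95, 196)  # half-open row span of both cords
    vc_width: int = 30
    valley_width: int = 6
    valley_gap: int = 2
    arytenoid_box: tuple[int, int, int, int] = (25, 66, 88, 168)  # r0,r1,c0,c1
    base_colors: dict = field(
        default_factory=lambda: {
            "background": (170, 110, 105),
            "glottis": (40, 22, 22),
            "vocal_cord": (225, 170, 160),
            "arytenoid": (235, 195, 185),
            "valley": (110, 60, 60),
        }
    )
    lpr: bool = False
    lpr_effect: LprEffect = field(default_factory=LprEffect)
    texture_sd: float = 6.0
    background_texture_sd: float = 2.0
    noise_sd: float = 2.0
    blur_sigma: float = 0.0
    illum_offset: float = 0.0
    rsi_mix: tuple[float, float, float] = (0.36, 0.51, 0.13)
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_size
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise InvalidParameterError("noise_sd and blur_sigma must be >= 0")
        for r, c in self.glottis_vertices:
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvalidParameterError("glottis vertex outside image")
        r0, r1, c0, c1 = self.arytenoid_box
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise InvalidParameterError("arytenoid box outside image")
        if not (0 <= self.vc_rows[0] < self.vc_rows[1] <= rows):
            raise InvalidParameterError("vocal-cord rows outside image")
        g_cols = [c for _, c in self.glottis_vertices]
        left_outer = min(g_cols) - self.vc_width
        right_outer = max(g_cols) + self.vc_width
        if left_outer - self.valley_gap - self.valley_width < 0:
            raise InvalidParameterError("left valley outside image")
        if right_outer + self.valley_gap + self.valley_width > cols:
            raise InvalidParameterError("right valley outside image")
        rows_overlap = self.vc_rows[0] < r1 and r0 < self.vc_rows[1]
        left_span = (left_outer, min(g_cols))
        right_span = (max(g_cols), right_outer)
        cols_overlap = any(
            lo < c1 and c0 < hi for lo, hi in (left_span, right_span)
        )
        if rows_overlap and cols_overlap:
            raise InvalidParameterError("vocal cords overlap the arytenoid block")


@dataclass
class PhantomSample:
    """A rendered frame, its ground-truth masks, class label and RSI score."""

    image: np.ndarray
    truth: RegionSet
    label: str
    rsi: int
    params: PhantomParams


def _geometry_masks(params: PhantomParams) -> dict[str, np.ndarray]:
    rows, cols = params.image_size
    shape = (rows, cols)

    glottis = np.zeros(shape, dtype=bool)
    vr = np.array([v[0] for v in params.glottis_vertices])
    vc = np.array([v[1] for v in params.glottis_vertices])
    rr, cc = draw_polygon(vr, vc, shape)
    glottis[rr, cc] = True

    g_cols = [c for _, c in params.glottis_vertices]
    r0, r1 = params.vc_rows
    left = np.zeros(shape, dtype=bool)
    left[r0:r1, min(g_cols) - params.vc_width : min(g_cols)] = True
    right = np.zeros(shape, dtype=bool)
    right[r0:r1, max(g_cols) : max(g_cols) + params.vc_width] = True
    left &= ~glottis
    right &= ~glottis

    valley = np.zeros(shape, dtype=bool)
    lo = min(g_cols) - params.vc_width - params.valley_gap
    valley[r0:r1, lo - params.valley_width : lo] = True
    hi = max(g_cols) + params.vc_width + params.valley_gap
    valley[r0:r1, hi : hi + params.valley_width] = True

    a0, a1, b0, b1 = params.arytenoid_box
    aryt = np.zeros(shape, dtype=bool)
    aryt[a0:a1, b0:b1] = True

    return {
        "glottis": glottis,
        "left_vc": left,
        "right_vc": right,
        "valley": valley,
        "arytenoid": aryt,
    }


def _draw_rsi(rng: np.random.Generator, lpr: bool, mix) -> int:
    if not lpr:
        return int(rng.integers(0, 13))
    bins = list(SEVERITY_BINS.values())
    probs = np.asarray(mix, dtype=np.float64)
    probs = probs / probs.sum()
    lo, hi = bins[rng.choice(3, p=probs)]
    return int(rng.integers(lo, hi + 1))


def render_phantom_image(params: PhantomParams) -> np.ndarray:
    """Render the RGB frame only (deterministic for a fixed seed)."""
    rng = np.random.default_rng(params.seed)
    masks = _geometry_masks(params)
    rows, cols = params.image_size
    img = np.empty((rows, cols, 3), dtype=np.float64)
    img[...] = params.base_colors["background"]
    for name in ("valley", "arytenoid", "left_vc", "right_vc", "glottis"):
        key = "vocal_cord" if name.endswith("_vc") else name
        img[masks[name]] = params.base_colors[key]

    if params.lpr:
        eff = params.lpr_effect
        cords = masks["left_vc"] | masks["right_vc"]
        img[..., 0][cords] += eff.vc_red_shift
        ycc = rgb_to_ycbcr(np.clip(img, 0, 255).astype(np.uint8)).astype(
            np.float64
        )
        ycc[..., 1][masks["arytenoid"]] += eff.aryt_cb_shift
        ycc[..., 2][masks["arytenoid"]] += eff.aryt_cr_shift
        img = ycbcr_to_rgb(ycc).astype(np.float64)

    # seeded speckle texture: strong inside cords/arytenoid, mild elsewhere
    speckle = rng.normal(0.0, 1.0, size=(rows, cols))
    amp = np.full((rows, cols), params.background_texture_sd)
    textured = masks["arytenoid"] | masks["left_vc"] | masks["right_vc"]
    amp[textured] = params.texture_sd
    if params.lpr:
        cords = masks["left_vc"] | masks["right_vc"]
        amp[cords] *= params.lpr_effect.vc_contrast_gain
    img += (speckle * amp)[..., None]

    if params.illum_offset:
        img += params.illum_offset
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    # blur last so a blurred frame is a blurred copy of the sharp one and
    # every sharpness score decreases monotonically with blur_sigma
    if params.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = gaussian_filter(img[..., ch], params.blur_sigma)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_phantom(params: PhantomParams | None = None) -> PhantomSample:
    """Render a phantom frame together with its ground truth and RSI."""
    params = params or PhantomParams()
    image = render_phantom_image(params)
    masks = _geometry_masks(params)
    truth = RegionSet(
        glottis=masks["glottis"],
        left_vc=masks["left_vc"],
        right_vc=masks["right_vc"],
        arytenoid=masks["arytenoid"],
    )
    rng = np.random.default_rng((params.seed, 0x51))
    rsi = _draw_rsi(rng, params.lpr, params.rsi_mix)
    label = LPR_LABEL if params.lpr else NON_LPR_LABEL
    return PhantomSample(image=image, truth=truth, label=label, rsi=rsi, params=params)


@dataclass
class DistractorSpec:
    """Distractor recipe for a frame stack."""

    blur_sigmas: tuple[float, ...] = (2.0, 3.0, 4.0)
    motion_lengths: tuple[int, ...] = ()
    n_nonthroat: int = 1
    nonthroat_color: tuple[int, int, int] = (110, 120, 130)


def _motion_blur(image: np.ndarray, length: int) -> np.ndarray:
    """Horizontal line motion blur of the given length (>= 2)."""
    img = image.astype(np.float64)
    acc = np.zeros_like(img)
    for s in range(length):
        acc += np.roll(img, s, axis=1)
    return np.clip(np.rint(acc / length), 0, 255).astype(np.uint8)


def make_frame_stack(
    params: PhantomParams | None = None,
    distractors: DistractorSpec | None = None,
) -> tuple[list[np.ndarray], int]:
    """A shuffled stack with exactly one sharp throat frame.

    Returns the frame list and the index of the sharp frame.  Distractors
    are Gaussian-blurred copies, motion-blurred copies and non-throat
    (low red fraction) frames; the shuffle order is seeded by the params.
    """
    params = params or PhantomParams()
    distractors = distractors or DistractorSpec()
    rng = np.random.default_rng((params.seed, 0xF4A3))
    sharp = render_phantom_image(params)

    frames: list[np.ndarray] = [sharp]
    for sigma in distractors.blur_sigmas:
        frames.append(render_phantom_image(replace(params, blur_sigma=sigma)))
    for length in distractors.motion_lengths:
        frames.append(_motion_blur(sharp, length))
    rows, cols = params.image_size
    for _ in range(distractors.n_nonthroat):
        flat = np.empty((rows, cols, 3), dtype=np.float64)
        flat[...] = distractors.nonthroat_color
        flat += rng.normal(0, 2.0, size=flat.shape)
        frames.append(np.clip(np.rint(flat), 0, 255).astype(np.uint8))

    order = rng.permutation(len(frames))
    stack = [frames[i] for i in order]
    truth_index = int(np.nonzero(order == 0)[0][0])
    return stack, truth_index


def make_feature_cohort(
    n_lpr: int,
    n_non: int,
    effect: float | dict[str, float] = 2.0,
    seed: int = 0,
    severity_gain: float = 0.0,
    rsi_mix: tuple[float, float, float] = (0.36, 0.51, 0.13),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gaussian feature cohort: (36-column table, labels, RSI scores).

    Baseline features are iid N(0, 1).  LPR samples get a mean shift (in sd
    units) on the five selected features only: a scalar ``effect`` applies
    uniformly, a dict gives per-feature shifts (features not mentioned get
    0).  ``severity_gain`` scales the shift by (1 + gain * bin_index) with
    bin_index 0/1/2 for primary/intermediate/severe, making severity
    classes separable when positive.
    """
    if n_lpr < 1 or n_non < 1:
        raise InvalidParameterError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_lpr + n_non
    data = rng.normal(0.0, 1.0, size=(n, 36))
    labels = np.array([LPR_LABEL] * n_lpr + [NON_LPR_LABEL] * n_non)
    rsi = np.array(
        [_draw_rsi(rng, lab == LPR_LABEL, rsi_mix) for lab in labels]
    )

    if isinstance(effect, dict):
        shifts = {name: float(effect.get(name, 0.0)) for name in FEATURE_NAMES}
    else:
        shifts = {name: float(effect) for name in SELECTED_FEATURES}
    bin_edges = SEVERITY_BINS
    for name, shift in shifts.items():
        if shift == 0.0:
            continue
        col = FEATURE_NAMES.index(name)
        for row in range(n_lpr):
            gain = 1.0
            if severity_gain:
                score = rsi[row]
                for b_idx, (lo, hi) in enumerate(bin_edges.values()):
                    if lo <= score <= hi:
                        gain = 1.0 + severity_gain * b_idx
                        break
            data[row, col] += shift * gain
    table = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    return table, labels, rsi
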
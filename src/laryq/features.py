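"""Hue and GLCM texture features of the segmented regions, and Fisher ranking.

The 36-entry feature vector combines, per region, six chromatic means
(R, G, B, HSV hue, Cb, Cr) and four texture statistics of the normalized
0-degree gray-level co-occurrence matrix (energy, contrast, correlation,
homogeneity).  Vocal-cord entries are element-wise max/min over the left
and right cord; six ratio features divide the cord means by the arytenoid
means.  Features are ranked for two-class separability with the Fisher
criterion f = (mu1 - mu2)^2 / (s1^2 + s2^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .compensation import rgb_to_ycbcr
from .errors import InvalidInputError

CHANNELS = ("R", "G", "B", "H", "Cb", "Cr")
GLCM_STATS = ("con", "eng", "cor", "hom")

#: Canonical order of the 36 feature names.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"A_{ch}" for ch in CHANNELS]
    + [f"VC_{ch} {mm}" for ch in CHANNELS for mm in ("max", "min")]
    + [f"VC/A_{ch}" for ch in CHANNELS]
    + [f"A_{st}" for st in GLCM_STATS]
    + [f"VC_{st} {mm}" for st in GLCM_STATS for mm in ("max", "min")]
)
assert len(FEATURE_NAMES) == 36

#: The five features with the strongest reported two-class separation,
#: used as the default classifier input set.
SELECTED_FEATURES: tuple[str, ...] = (
    "A_eng",
    "A_Cb",
    "A_Cr",
    "VC_con max",
    "VC_R max",
)


def _masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if values.shape[:2] != mask.shape:
        raise InvalidInputError("image and mask dimensions differ")
    if mask.sum() == 0:
        raise InvalidInputError("empty mask")
    return values[mask]


def mean_channel(image: np.ndarray, mask: np.ndarray, channel: str) -> float:
    """Mean of a chromatic channel over the masked pixels.

    H is averaged circularly (vector mean of hue angles, degrees in
    [0, 360)); the others are plain means on the 8-bit scale (Cb and Cr are
    full-range with achromatic at 128).
    """
    image = np.asarray(image)
    if channel in ("R", "G", "B"):
        idx = "RGB".index(channel)
        return float(_masked(image[..., idx].astype(np.float64), mask).mean())
    if channel == "H":
        hsv = rgb2hsv(image)
        angles = _masked(hsv[..., 0].astype(np.float64), mask) * 2 * np.pi
        mean_vec = np.exp(1j * angles).mean()
        deg = np.degrees(np.angle(mean_vec)) % 360.0
        return float(deg)
    if channel in ("Cb", "Cr"):
        ycc = rgb_to_ycbcr(image)
        idx = 1 if channel == "Cb" else 2
        return float(_masked(ycc[..., idx], mask).mean())
    raise InvalidInputError(f"unknown channel {channel!r}")


@dataclass
class Glcm:
    """Normalized gray-level co-occurrence matrix."""

    p: np.ndarray
    levels: int
    distance: int = 1
    angle: float = 0.0


def quantize_gray(gray: np.ndarray, levels: int = 8) -> np.ndarray:
    """Linear quantization of 8-bit gray values into ``levels`` bins."""
    gray = np.asarray(gray)
    q = (gray.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1)


def glcm_matrix(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    distance: int = 1,
    angle: float = 0.0,
    levels: int = 8,
) -> Glcm:
    """Masked, symmetric, normalized GLCM at 0 degrees.

    Counts horizontal pixel pairs (p, p + (0, distance)) with both members
    inside the mask, in both orderings, then normalizes the matrix to sum 1.
    """
    if angle != 0.0:
        raise InvalidInputError("only the 0-degree co-occurrence is supported")
    if distance < 1:
        raise InvalidInputError("distance must be >= 1")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise InvalidInputError("expected a 2-D gray image")
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise InvalidInputError("mask dimensions differ from image")

    q = quantize_gray(gray, levels)
    left = q[:, :-distance]
    right = q[:, distance:]
    valid = mask[:, :-distance] & mask[:, distance:]
    if valid.sum() == 0:
        raise InvalidInputError("no valid horizontal pixel pair in mask")
    i = left[valid].ravel()
    j = right[valid].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)  # symmetrize
    return Glcm(p=counts / counts.sum(), levels=levels, distance=distance)


def _check_normalized(P: Glcm | np.ndarray) -> np.ndarray:
    p = P.p if isinstance(P, Glcm) else np.asarray(P, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidInputError("co-occurrence matrix is not normalized")
    return p


def glcm_energy(P: Glcm | np.ndarray) -> float:
    """Sum of squared entries; 1 iff the region has a single gray pair."""
    p = _check_normalized(P)
    return float((p**2).sum())


def glcm_contrast(P: Glcm | np.ndarray) -> float:
    """sum (i - j)^2 p_ij; 0 for a constant region, <= (k-1)^2."""
    p = _check_normalized(P)
    k = p.shape[0]
    i, j = np.indices((k, k))
    return float(((i - j) ** 2 * p).sum())


def glcm_correlation(P: Glcm | np.ndarray) -> float:
    """Marginal-normalized pair correlation; 0 when a marginal sd is 0."""
    p = _check_normalized(P)
    k = p.shape[0]
    idx = np.arange(k, dtype=np.float64)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = (idx * pi).sum()
    mu_j = (idx * pj).sum()
    var_i = ((idx - mu_i) ** 2 * pi).sum()
    var_j = ((idx - mu_j) ** 2 * pj).sum()
    if var_i <= 0 or var_j <= 0:
        return 0.0
    ii, jj = np.indices((k, k))
    cov = ((ii - mu_i) * (jj - mu_j) * p).sum()
    return float(cov / np.sqrt(var_i * var_j))


def glcm_homogeneity(P: Glcm | np.ndarray) -> float:
    """sum p_ij / (1 + |i - j|) (inverse difference)."""
    p = _check_normalized(P)
    k = p.shape[0]
    i, j = np.indices((k, k))
    return float((p / (1.0 + np.abs(i - j))).sum())


_GLCM_FUNCS = {
    "con": glcm_contrast,
    "eng": glcm_energy,
    "cor": glcm_correlation,
    "hom": glcm_homogeneity,
}


def extract_features(image: np.ndarray, regions) -> pd.Series:
    """The 36-entry feature vector for a segmented frame.

    ``regions`` provides non-empty boolean masks ``glottis``, ``left_vc``,
    ``right_vc`` and ``arytenoid``; hue/texture statistics are taken from
    the arytenoid and the two cord masks, cord entries reduced element-wise
    to max/min, and ratio entries divide the cord mean (average of left and
    right) by the arytenoid mean.
    """
    from .compensation import luma  # local import to keep module deps flat

    for name in ("left_vc", "right_vc", "arytenoid"):
        mask = np.asarray(getattr(regions, name), dtype=bool)
        if mask.sum() == 0:
            raise InvalidInputError(f"region {name!r} is empty")

    gray = np.clip(np.rint(luma(image)), 0, 255).astype(np.uint8)
    out: dict[str, float] = {}

    a_mask = regions.arytenoid
    hue = {}
    for ch in CHANNELS:
        a = mean_channel(image, a_mask, ch)
        lv = mean_channel(image, regions.left_vc, ch)
        rv = mean_channel(image, regions.right_vc, ch)
        out[f"A_{ch}"] = a
        out[f"VC_{ch} max"] = max(lv, rv)
        out[f"VC_{ch} min"] = min(lv, rv)
        hue[ch] = (a, lv, rv)
    for ch in CHANNELS:
        a, lv, rv = hue[ch]
        out[f"VC/A_{ch}"] = ((lv + rv) / 2.0) / a if a != 0 else np.inf

    a_glcm = glcm_matrix(gray, a_mask)
    l_glcm = glcm_matrix(gray, regions.left_vc)
    r_glcm = glcm_matrix(gray, regions.right_vc)
    for st, func in _GLCM_FUNCS.items():
        out[f"A_{st}"] = func(a_glcm)
        lv, rv = func(l_glcm), func(r_glcm)
        out[f"VC_{st} max"] = max(lv, rv)
        out[f"VC_{st} min"] = min(lv, rv)

    return pd.Series([out[name] for name in FEATURE_NAMES], index=FEATURE_NAMES)


@dataclass
class FisherScore:
    feature: str
    f: float


def fisher_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher criterion (mu1 - mu2)^2 / (s1^2 + s2^2).

    Uses per-class sample variances (ddof=1).  Returns 0 when the class
    means are equal; +inf when both variances are 0 but the means differ.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise InvalidInputError("exactly two classes are required")
    g1 = values[labels == classes[0]]
    g2 = values[labels == classes[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidInputError("need at least 2 samples per class")
    num = (g1.mean() - g2.mean()) ** 2
    den = g1.var(ddof=1) + g2.var(ddof=1)
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


def rank_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    top_k: int = 5,
    use_default_selection: bool = False,
) -> tuple[list[FisherScore], list[str]]:
    """Fisher scores for all 36 features, descending, plus a selection.

    With ``use_default_selection`` the returned selection is the fixed
    :data:`SELECTED_FEATURES` set; otherwise it is the ``top_k`` best
    scoring features.
    """
    missing = [n for n in FEATURE_NAMES if n not in table.columns]
    if missing:
        raise InvalidInputError(f"missing feature columns: {missing[:3]}...")
    scores = [
        FisherScore(name, fisher_score(table[name].to_numpy(), labels))
        for name in FEATURE_NAMES
    ]
    scores.sort(key=lambda s: -s.f)
    if use_default_selection:
        selected = list(SELECTED_FEATURES)
    else:
        selected = [s.feature for s in scores[:top_k]]
    return scores, selected
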
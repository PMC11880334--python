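"""Gray-level co-occurrence matrices and the 10-value texture feature vector.

A GLCM P(i, j) is the normalized count of pixel pairs with quantized
intensities i and j at a fixed spatial offset. Two features are derived:

    contrast    = sum (i - j)^2 P(i, j)
    correlation = sum (i - mu_i)(j - mu_j) P(i, j) / (sigma_i sigma_j)

The feature vector uses two source planes — luminance L and chroma magnitude
sqrt(u^2 + v^2) — and for each contributes contrast and correlation of both
the plane's GLCM and the squared plane's GLCM (each averaged over the four
offsets 0/45/90/135 degrees) plus the plane mean: 5 values per source, 10
total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import LuvImage
from .errors import ValidationError

# angle -> (row offset, col offset) at distance d, (row, col) origin top-left
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FEATURE_NAMES = [f"{src}_{feat}" for src in ("L", "C")
                 for feat in ("contrast", "correlation",
                              "contrast_sq", "correlation_sq", "mean")]


@dataclass
class GlcmMatrix:
    """A normalized co-occurrence matrix with its construction parameters."""

    p: np.ndarray          # G x G, entries >= 0, sums to 1
    levels: int
    distance: int
    angle: int             # degrees, one of 0/45/90/135
    symmetric: bool


@dataclass
class TextureFeatures:
    """The 10-value luminance-chroma feature vector."""

    values: np.ndarray     # length 10, ordered as FEATURE_NAMES
    levels: int
    distance: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def quantize_levels(plane: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin the plane's [min, max] range into ``levels`` indices.

    A constant plane maps to all zeros.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    p = np.asarray(plane, dtype=np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.zeros(p.shape, dtype=np.int64)
    idx = np.floor((p - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(idx, 0, levels - 1)


def compute_glcm(indices: np.ndarray, distance: int = 1, angle: int = 0,
                 symmetric: bool = True, levels: int | None = None) -> GlcmMatrix:
    """Count co-occurring index pairs at the given offset and normalize.

    Offsets follow the (row, col) convention: 0° -> (0, d), 45° -> (-d, d),
    90° -> (-d, 0), 135° -> (-d, -d). With ``symmetric`` each pair is also
    counted in reverse.
    """
    idx = np.asarray(indices)
    if not np.issubdtype(idx.dtype, np.integer):
        raise ValidationError("indices must be integer (use quantize_levels first)")
    if angle not in OFFSETS:
        raise ValidationError(f"angle must be one of {sorted(OFFSETS)}")
    if distance < 1:
        raise ValidationError("distance must be >= 1")
    G = levels if levels is not None else int(idx.max()) + 1
    dr, dc = (o * distance for o in OFFSETS[angle])
    H, W = idx.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValidationError(f"offset ({dr},{dc}) does not fit a {H}x{W} image")
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = idx[r0:r1, c0:c1].ravel()
    b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * G + b, minlength=G * G).reshape(G, G).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return GlcmMatrix(p=counts / total, levels=G, distance=distance,
                      angle=angle, symmetric=symmetric)


def glcm_contrast(m: GlcmMatrix) -> float:
    """sum (i - j)^2 P(i, j): 0 for a constant image, large for sharp texture."""
    i, j = np.indices(m.p.shape)
    return float(((i - j) ** 2 * m.p).sum())


def glcm_correlation(m: GlcmMatrix) -> float:
    """Normalized covariance of the pair distribution, in [-1, 1].

    Degenerate marginals (a single occupied level) have no linear structure
    to measure; the convention here is 0.
    """
    G = m.p.shape[0]
    lv = np.arange(G, dtype=np.float64)
    pi = m.p.sum(axis=1)
    pj = m.p.sum(axis=0)
    mu_i, mu_j = lv @ pi, lv @ pj
    var_i = (lv - mu_i) ** 2 @ pi
    var_j = (lv - mu_j) ** 2 @ pj
    if var_i <= 0 or var_j <= 0:
        return 0.0
    cov = ((lv[:, None] - mu_i) * (lv[None, :] - mu_j) * m.p).sum()
    return float(cov / np.sqrt(var_i * var_j))


def _plane_features(plane: np.ndarray, levels: int, distance: int) -> list[float]:
    """contrast, correlation for plane and plane^2 (offset-averaged), + mean."""
    out = []
    for src in (plane, plane.astype(np.float64) ** 2):
        idx = quantize_levels(src, levels)
        cons, cors = [], []
        for angle in OFFSETS:
            g = compute_glcm(idx, distance=distance, angle=angle, symmetric=True,
                             levels=levels)
            cons.append(glcm_contrast(g))
            cors.append(glcm_correlation(g))
        out += [float(np.mean(cons)), float(np.mean(cors))]
    out.append(float(np.mean(plane)))
    return out


def feature_vector(image: LuvImage, levels: int = 8, distance: int = 1) -> TextureFeatures:
    """The 10-value texture descriptor of a Luv image.

    Averaging over the four offsets makes the descriptor invariant to image
    transposition and 90-degree rotation.
    """
    H, W = image.shape
    if H < 2 * distance or W < 2 * distance:
        raise ValidationError("image too small for the requested offset distance")
    values = _plane_features(image.L, levels, distance) \
        + _plane_features(image.chroma(), levels, distance)
    return TextureFeatures(values=np.asarray(values), levels=levels, distance=distance)


def offset_sweep(plane: np.ndarray, levels: int, distances) -> dict[int, tuple[float, float]]:
    """Offset-resolved (contrast, correlation) at 0° for distance sweeps."""
    idx = quantize_levels(plane, levels)
    out = {}
    for d in distances:
        g = compute_glcm(idx, distance=d, angle=0, symmetric=True, levels=levels)
        out[int(d)] = (glcm_contrast(g), glcm_correlation(g))
    return out
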
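"""RGB <-> CIE 1976 L*u*v* conversion and Gaussian low-pass filtering.

The working color representation of the whole pipeline is the Luv image:
L* carries luminance in [0, 100], u* and v* carry chrominance along the
green-red and blue-yellow axes. sRGB companding and the D65 white point are
assumed (consumer cameras); the white point is taken as M @ [1, 1, 1] of the
sRGB->XYZ matrix itself so that the neutral axis maps exactly to u* = v* = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import RgbImage

# sRGB (IEC 61966-2-1) linear RGB -> XYZ
_M_RGB2XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)
_WHITE = _M_RGB2XYZ @ np.ones(3)         # D65 white, self-consistent with the matrix
_EPS_CIE = 216.0 / 24389.0               # (6/29)^3
_KAPPA = 24389.0 / 27.0


@dataclass
class LuvImage:
    """Per-pixel (L*, u*, v*) planes; L in [0, 100], neutral pixels at u=v=0."""

    L: np.ndarray
    u: np.ndarray
    v: np.ndarray
    white_point: str = "D65"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.L.shape == self.u.shape == self.v.shape):
            raise ValidationError("L, u, v planes must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def chroma(self) -> np.ndarray:
        """Chroma magnitude sqrt(u^2 + v^2), the 'color' source plane."""
        return np.hypot(self.u, self.v)


@dataclass
class GaussianKernel:
    """A normalized, centrally symmetric isotropic Gaussian kernel."""

    size: int
    sigma: float
    weights: np.ndarray


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1 / 2.4) - 0.055)


def _uv_prime(X, Y, Z):
    denom = X + 15.0 * Y + 3.0 * Z
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, 4.0 * X / safe, 0.0), np.where(denom > 0, 9.0 * Y / safe, 0.0)


_UN_PRIME, _VN_PRIME = _uv_prime(*_WHITE)


def rgb_to_luv(image: RgbImage) -> LuvImage:
    """Convert an 8-bit RGB image to CIE 1976 L*u*v*.

    Black maps to (0, 0, 0); any gray maps onto the neutral axis (u = v = 0);
    reference white maps to L = 100.
    """
    rgb = image.pixels.astype(np.float64) / 255.0
    lin = _srgb_to_linear(rgb)
    XYZ = lin @ _M_RGB2XYZ.T
    X, Y, Z = XYZ[..., 0], XYZ[..., 1], XYZ[..., 2]
    yr = Y / _WHITE[1]
    L = np.where(yr > _EPS_CIE, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)
    up, vp = _uv_prime(X, Y, Z)
    u = 13.0 * L * (up - _UN_PRIME)
    v = 13.0 * L * (vp - _VN_PRIME)
    # L = 0 (Y = 0) pixels have undefined chromaticity; define u = v = 0 there
    dark = L <= 0
    u[dark] = 0.0
    v[dark] = 0.0
    return LuvImage(L=L, u=u, v=v)


def luv_to_rgb(image: LuvImage) -> RgbImage:
    """Inverse transform back to 8-bit RGB, clipping channels to [0, 255]."""
    L, u, v = image.L, image.u, image.v
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(L > 0, u / (13.0 * L) + _UN_PRIME, _UN_PRIME)
        vp = np.where(L > 0, v / (13.0 * L) + _VN_PRIME, _VN_PRIME)
    Y = np.where(L > _KAPPA * _EPS_CIE, ((L + 16.0) / 116.0) ** 3, L / _KAPPA) * _WHITE[1]
    vp_safe = np.where(vp > 0, vp, 1.0)
    X = np.where(vp > 0, Y * 9.0 * up / (4.0 * vp_safe), 0.0)
    Z = np.where(vp > 0, Y * (12.0 - 3.0 * up - 20.0 * vp) / (4.0 * vp_safe), 0.0)
    lin = np.stack([X, Y, Z], axis=-1) @ _M_XYZ2RGB.T
    rgb = np.clip(np.rint(_linear_to_srgb(lin) * 255.0), 0, 255).astype(np.uint8)
    return RgbImage(pixels=rgb)


def make_gaussian_kernel(size: int, sigma: float) -> GaussianKernel:
    """Build the isotropic Gaussian kernel on integer offsets, normalized to sum 1.

    Weights are proportional to exp(-(x^2 + y^2) / (2 sigma^2)) evaluated on the
    integer grid centered at 0.
    """
    if size < 3 or size % 2 == 0:
        raise ValidationError(f"kernel size must be an odd integer >= 3, got {size}")
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(x, x)
    w = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    w /= w.sum()
    return GaussianKernel(size=size, sigma=sigma, weights=w)


def gaussian_filter(plane: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """2-D convolution with the kernel, reflective boundary padding, same shape."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.shape[0] < kernel.size or plane.shape[1] < kernel.size:
        raise ValidationError("plane smaller than the kernel")
    return ndimage.convolve(plane, kernel.weights, mode="reflect")


def smooth_luv(image: LuvImage, kernel: GaussianKernel) -> LuvImage:
    """Filter each of the L, u, v planes independently."""
    return LuvImage(
        L=gaussian_filter(image.L, kernel),
        u=gaussian_filter(image.u, kernel),
        v=gaussian_filter(image.v, kernel),
        white_point=image.white_point,
        notes=image.notes + [f"gaussian {kernel.size}x{kernel.size} sigma={kernel.sigma}"],
    )
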
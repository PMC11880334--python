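"""Seeded synthetic burn phantoms with ground-truth masks.

Clinical burn photographs carry protected patient data, so the pipeline is
exercised on phantoms: images with a nested-ellipse lesion whose rings are
the three burn-depth classes (superficial outermost, deep innermost, matching
how depth grades from the wound edge to its core), surrounded by healthy
skin. Each class draws its pixels from a class-specific RGB palette plus
spatially correlated noise whose correlation length shrinks with depth —
deeper tissue looks both darker and rougher, the qualitative premise the
segmentation and texture stages rely on.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import DEEP, DERMAL, HEALTHY, SUPERFICIAL, LabelImage, RgbImage
from .kinetics import PlasmaCurve

#: per-class mean RGB and channel noise std (8-bit units)
DEFAULT_PALETTE = {
    HEALTHY: ((205, 170, 150), 8.0),
    SUPERFICIAL: ((230, 160, 140), 10.0),
    DERMAL: ((200, 90, 80), 12.0),
    DEEP: ((120, 40, 35), 10.0),
}

#: per-class correlation length of the texture noise, in pixels
#: (decreasing with depth: deeper tissue is rougher at the pixel scale)
DEFAULT_TEXTURE_SCALE = {HEALTHY: 3.0, SUPERFICIAL: 2.0, DERMAL: 1.2, DEEP: 0.5}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic burn image.

    ``fractions`` are the target canvas-area fractions of the three burn
    classes; the remainder is healthy skin. ``geometry`` is "ellipse" for
    nested elliptical rings or "bands" for a degenerate row-banded mask whose
    class areas are pixel-exact (useful for worked examples).
    """

    size: tuple[int, int] = (256, 256)
    fractions: dict[int, float] = field(
        default_factory=lambda: {SUPERFICIAL: 0.20, DERMAL: 0.15, DEEP: 0.15})
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    texture_scale: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE_SCALE))
    geometry: str = "ellipse"
    rotation: float = 0.0          # lesion rotation, radians
    center: tuple[float, float] | None = None   # (row, col); canvas center if None
    aspect: float = 1.3            # lesion row/col axis ratio
    seed: int = 0

    def __post_init__(self):
        for c, f in self.fractions.items():
            if not (0 <= f <= 1):
                raise ValidationError(f"fraction for class {c} outside [0, 1]")
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise ValidationError("class fractions must sum to at most 1")
        if self.geometry not in ("ellipse", "bands"):
            raise ValidationError("geometry must be 'ellipse' or 'bands'")


@dataclass
class PhantomDataset:
    """A collection of phantoms with dominant-class labels."""

    images: list[RgbImage]
    masks: list[LabelImage]
    labels: np.ndarray      # dominant burn class per image, values in {1, 2, 3}
    seed: int

    def __len__(self) -> int:
        return len(self.images)


def _ellipse_mask(shape, center, axes, rotation) -> np.ndarray:
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    r = rr - center[0]
    c = cc - center[1]
    cosr, sinr = np.cos(rotation), np.sin(rotation)
    x = r * cosr + c * sinr
    y = -r * sinr + c * cosr
    return (x / axes[0]) ** 2 + (y / axes[1]) ** 2 <= 1.0


def _nested_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the nested-ellipse lesion; rings in depth order out->in."""
    H, W = spec.size
    center = spec.center or ((H - 1) / 2.0, (W - 1) / 2.0)
    order = [SUPERFICIAL, DERMAL, DEEP]
    fr = [spec.fractions.get(c, 0.0) for c in order]
    mask = np.zeros((H, W), dtype=np.int64)
    # cumulative area from the inside out: deep, deep+dermal, all burn
    cum = np.cumsum(fr[::-1])[::-1]     # cum[k] = area of ring k and everything inside
    for cls, area_frac in zip(order, cum):
        if area_frac <= 0:
            continue
        area = area_frac * H * W
        b = np.sqrt(area / (np.pi * spec.aspect))   # col semi-axis
        a = spec.aspect * b                         # row semi-axis
        if a > (H - 1) / 2.0 + 0.5 or b > (W - 1) / 2.0 + 0.5:
            raise ValidationError(
                f"lesion ellipse ({a:.1f} x {b:.1f}) exceeds the {H}x{W} canvas")
        ell = _ellipse_mask((H, W), center, (a, b), spec.rotation)
        mask[ell] = cls
    return mask


def _band_mask(spec: PhantomSpec) -> np.ndarray:
    """Row-major banded mask with pixel-exact class counts."""
    H, W = spec.size
    total = H * W
    flat = np.full(total, HEALTHY, dtype=np.int64)
    pos = 0
    for cls in (SUPERFICIAL, DERMAL, DEEP):
        n = int(round(spec.fractions.get(cls, 0.0) * total))
        flat[pos:pos + n] = cls
        pos += n
    return flat.reshape(H, W)


def _correlated_noise(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with correlation length ``scale`` pixels."""
    white = rng.standard_normal(shape)
    if scale <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=scale, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_phantom(spec: PhantomSpec) -> tuple[RgbImage, LabelImage]:
    """Render one phantom and its ground-truth mask, deterministically."""
    H, W = spec.size
    mask = _band_mask(spec) if spec.geometry == "bands" else _nested_mask(spec)
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((H, W, 3), dtype=np.float64)
    for cls, (mean_rgb, sd) in spec.palette.items():
        noise = np.stack([
            _correlated_noise((H, W), spec.texture_scale[cls], rng)
            for _ in range(3)], axis=-1)
        sel = mask == cls
        img[sel] = np.asarray(mean_rgb)[None, :] + sd * noise[sel]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RgbImage(pixels=pixels, source=f"phantom(seed={spec.seed})"), \
        LabelImage(labels=mask)


def generate_dataset(n: int = 90, balance: dict[int, float] | None = None,
                     seed: int = 42, size: tuple[int, int] = (256, 256)) -> PhantomDataset:
    """Generate ``n`` phantoms with dominant-class labels.

    ``balance`` maps burn class -> share of the dataset (default: equal
    thirds). Each image's lesion is dominated by its assigned class, with
    smaller admixtures of the other two depths, randomized geometry, and a
    per-image seed derived from the dataset seed.
    """
    if n < 9:
        raise ValidationError("need n >= 9 for stratified downstream splits")
    balance = balance or {SUPERFICIAL: 1 / 3, DERMAL: 1 / 3, DEEP: 1 / 3}
    if abs(sum(balance.values()) - 1.0) > 1e-9:
        raise ValidationError("balance shares must sum to 1")
    counts = {c: int(np.floor(f * n)) for c, f in balance.items()}
    leftover = n - sum(counts.values())
    for c in sorted(balance, key=lambda c: -balance[c])[:leftover]:
        counts[c] += 1
    if min(counts.values()) < 3:
        raise ValidationError("every class needs at least 3 images; adjust balance")
    rng = np.random.default_rng(seed)
    images, masks, labels = [], [], []
    for cls in sorted(counts):
        for _ in range(counts[cls]):
            dom = rng.uniform(0.30, 0.40)
            minor = rng.uniform(0.03, 0.07, size=2)
            fractions = {c: 0.0 for c in (SUPERFICIAL, DERMAL, DEEP)}
            fractions[cls] = dom
            others = [c for c in (SUPERFICIAL, DERMAL, DEEP) if c != cls]
            for c, f in zip(others, minor):
                fractions[c] = float(f)
            spec = PhantomSpec(size=size, fractions=fractions,
                               rotation=float(rng.uniform(0, np.pi)),
                               aspect=float(rng.uniform(1.05, 1.25)),
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
            img, mask = generate_phantom(spec)
            images.append(img)
            masks.append(mask)
            labels.append(cls)
    return PhantomDataset(images=images, masks=masks,
                          labels=np.asarray(labels, dtype=np.int64), seed=seed)


def generate_plasma_curve(kind: str, params: dict, grid: np.ndarray) -> PlasmaCurve:
    """Reference plasma input: constant, or a biexponential decay
    a1 e^{-m1 t} + a2 e^{-m2 t} (the standard population-based form)."""
    t = np.asarray(grid, dtype=np.float64)
    if kind == "constant":
        c = float(params.get("c", 1.0))
        if c < 0:
            raise ValidationError("constant amplitude must be nonnegative")
        cp = np.full_like(t, c)
    elif kind == "biexponential":
        a1, a2 = float(params.get("a1", 3.99)), float(params.get("a2", 4.78))
        m1, m2 = float(params.get("m1", 0.144)), float(params.get("m2", 0.0111))
        if a1 < 0 or a2 < 0:
            raise ValidationError("amplitudes must be nonnegative")
        cp = a1 * np.exp(-m1 * t) + a2 * np.exp(-m2 * t)
    else:
        raise ValidationError(f"unknown plasma curve kind {kind!r}")
    return PlasmaCurve(times=t, cp=cp)
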
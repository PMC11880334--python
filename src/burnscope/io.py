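"""Image and label-mask readers/writers.

All images use (row, col) coordinates with the origin at the top-left corner.
Photographs are 8-bit RGB; label masks are single-channel PNGs holding the
integer burn-depth codes 0 (healthy), 1 (superficial), 2 (superficial-dermal),
3 (deep-dermal / full-thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ValidationError

#: burn-depth label codes, in increasing depth of tissue damage
HEALTHY, SUPERFICIAL, DERMAL, DEEP = 0, 1, 2, 3
CLASS_NAMES = {HEALTHY: "healthy", SUPERFICIAL: "superficial",
               DERMAL: "dermal", DEEP: "deep"}
VALID_LABELS = frozenset(CLASS_NAMES)


@dataclass
class RgbImage:
    """An 8-bit RGB photograph with provenance notes."""

    pixels: np.ndarray  # uint8, shape (H, W, 3)
    source: str | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"RgbImage needs (H, W, 3) pixels, got {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValidationError(f"RgbImage must be at least 8x8, got {px.shape[:2]}")
        if px.dtype != np.uint8:
            raise ValidationError(f"RgbImage pixels must be uint8, got {px.dtype}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelImage:
    """A per-pixel integer class map.

    Segmentation stages may emit arbitrary positive cluster labels; burn-depth
    maps use the codes in :data:`CLASS_NAMES`.
    """

    labels: np.ndarray  # integer, shape (H, W)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"LabelImage needs a 2-D array, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValidationError(f"LabelImage needs integer labels, got {lab.dtype}")
        self.labels = lab.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def read_image(path: str | Path) -> RgbImage:
    """Read an 8-bit RGB image (PNG/JPEG/TIFF).

    Grayscale inputs are promoted to 3 channels; an alpha channel is dropped;
    16-bit inputs are rescaled to [0, 255] by an 8-bit right shift, and the
    rescaling is recorded in the image's provenance notes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # non-image content
        raise FormatError(f"cannot decode {path} as an image: {exc}") from exc
    notes: list[str] = []
    arr = np.asarray(raw)
    if arr.dtype == np.uint16:
        arr = (arr >> 8).astype(np.uint8)
        notes.append("16-bit input right-shifted to 8-bit")
    elif arr.dtype != np.uint8:
        raise FormatError(f"unsupported pixel depth {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
        notes.append("grayscale promoted to 3 channels")
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
        notes.append("alpha channel dropped")
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    return RgbImage(pixels=arr, source=str(path), notes=notes)


def write_image(path: str | Path, image: RgbImage) -> None:
    iio.imwrite(Path(path), image.pixels)


def read_label_mask(path: str | Path) -> LabelImage:
    """Read a single-channel PNG label mask with codes in {0, 1, 2, 3}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"cannot decode {path} as a label mask: {exc}") from exc
    if arr.ndim != 2:
        raise ValidationError(f"label mask must be single-channel, got shape {arr.shape}")
    bad = set(np.unique(arr).tolist()) - VALID_LABELS
    if bad:
        raise ValidationError(
            f"label mask {path} contains invalid class code(s) {sorted(bad)}; "
            f"allowed codes are {sorted(VALID_LABELS)}")
    return LabelImage(labels=arr.astype(np.int64))


def write_label_mask(path: str | Path, mask: LabelImage) -> None:
    bad = set(np.unique(mask.labels).tolist()) - VALID_LABELS
    if bad:
        raise ValidationError(f"mask contains non burn-depth codes {sorted(bad)}")
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))
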
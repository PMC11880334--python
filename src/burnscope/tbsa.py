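"""Per-sample TBSA reporting.

"TBSA" here is the per-sample convention: the analyzed sample is 100% and
each burn-depth class is reported as its share of the sample's pixels. This
deliberately differs from the clinical rule-of-nines TBSA (fraction of the
whole body surface), which is out of scope; the healthy/background class is
always included so the percentages conserve to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .color import LuvImage
from .errors import ValidationError
from .io import CLASS_NAMES, DEEP, DERMAL, HEALTHY, SUPERFICIAL, LabelImage

#: overlay colors per class (R, G, B): skin-tone, yellow, blue, red
OVERLAY_COLORS = {
    HEALTHY: (205, 170, 150),
    SUPERFICIAL: (255, 215, 0),
    DERMAL: (30, 80, 220),
    DEEP: (220, 30, 30),
}


@dataclass
class TbsaReport:
    """Class-area percentages of one sample (sample area = 100%)."""

    percent: dict[str, float]
    counts: dict[str, int]
    total_pixels: int
    sample_id: str = "sample"

    def as_dict(self) -> dict:
        return {"sample": self.sample_id, "percent": self.percent,
                "counts": self.counts, "total_pixels": self.total_pixels}


@dataclass
class DepthHistogram:
    """Per-class 256-bin histograms of L values, with merged peak lists."""

    histograms: dict[str, np.ndarray]
    peaks: dict[str, list[float]]
    empty_classes: list[str] = field(default_factory=list)


def tbsa_percentages(labels: LabelImage, sample_id: str = "sample") -> TbsaReport:
    """Exact per-class pixel shares: percent_c = 100 * count_c / total."""
    lab = labels.labels
    total = lab.size
    if total == 0:
        raise ValidationError("empty label image")
    percent, counts = {}, {}
    for code, name in CLASS_NAMES.items():
        c = int((lab == code).sum())
        counts[name] = c
        percent[name] = 100.0 * c / total
    return TbsaReport(percent=percent, counts=counts, total_pixels=total,
                      sample_id=sample_id)


def depth_histograms(image: LuvImage, labels: LabelImage,
                     zth: int = 0, dth: float = 16.0) -> DepthHistogram:
    """L-plane histogram per burn-depth class.

    L values are binned at integer resolution on [0, 255] (L occupies the
    lower 101 bins). Bins below ``zth`` are zeroed (dark-pixel suppression);
    peaks closer than ``dth`` are merged (count-weighted) in the reported
    peak list. A class whose histogram empties out is flagged.
    """
    if image.shape != labels.shape:
        raise ValidationError(
            f"image {image.shape} and labels {labels.shape} shapes differ")
    L = np.clip(np.rint(image.L), 0, 255).astype(np.int64)
    hists, peaks, empty = {}, {}, []
    for code, name in CLASS_NAMES.items():
        sel = labels.labels == code
        h = np.bincount(L[sel].ravel(), minlength=256).astype(np.int64)
        if zth > 0:
            h[:zth] = 0
        hists[name] = h
        if h.sum() == 0:
            if sel.any():
                empty.append(name)
            peaks[name] = []
            continue
        idx, props = find_peaks(np.concatenate([[0], h, [0]]).astype(float))
        idx = idx - 1
        order = idx[np.argsort(-h[idx], kind="stable")]
        merged: list[float] = []
        weights: list[float] = []
        for i in order:
            pos, w = float(i), float(h[i])
            if merged:
                gaps = np.abs(np.asarray(merged) - pos)
                j = int(np.argmin(gaps))
                if gaps[j] < dth:
                    tot = weights[j] + w
                    merged[j] = (merged[j] * weights[j] + pos * w) / tot
                    weights[j] = tot
                    continue
            merged.append(pos)
            weights.append(w)
        peaks[name] = sorted(merged)
    return DepthHistogram(histograms=hists, peaks=peaks, empty_classes=empty)


def class_overlay(labels: LabelImage) -> np.ndarray:
    """Color-coded (H, W, 3) overlay: yellow/blue/red for the burn depths."""
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for code, color in OVERLAY_COLORS.items():
        out[labels.labels == code] = color
    return out


def render_report(report: TbsaReport, hist: DepthHistogram | None,
                  overlay: LabelImage, out_dir: str | Path) -> dict[str, Path]:
    """Write the JSON report, a pie chart (SVG) and the color overlay (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import imageio.v3 as iio
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    payload = report.as_dict()
    if hist is not None:
        payload["peaks"] = {k: [round(p, 3) for p in v] for k, v in hist.peaks.items()}
    paths["json"] = out / f"{report.sample_id}_tbsa.json"
    paths["json"].write_text(json.dumps(payload, indent=2))

    nonzero = {k: v for k, v in report.percent.items() if v > 0}
    fig, ax = plt.subplots(figsize=(4, 4))
    colors = {CLASS_NAMES[c]: np.asarray(col) / 255.0 for c, col in OVERLAY_COLORS.items()}
    ax.pie(list(nonzero.values()), labels=list(nonzero.keys()),
           colors=[colors[k] for k in nonzero], autopct="%1.1f%%")
    ax.set_title(f"{report.sample_id}: burn-depth shares")
    paths["pie"] = out / f"{report.sample_id}_tbsa_pie.svg"
    fig.savefig(paths["pie"])
    plt.close(fig)

    paths["overlay"] = out / f"{report.sample_id}_overlay.png"
    iio.imwrite(paths["overlay"], class_overlay(overlay))
    return paths
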
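"""Reference-region (RR) histogram segmentation.

The RR method segments a grayscale plane by its intensity histogram:
quantize while discarding dark pixels below Z_th, take histogram peaks as
candidate cluster centers, merge peaks closer than D_th, then label every
pixel by its nearest center — first within a similarity threshold, then with
the threshold raised so no pixel is left unlabeled. Pixels that still have no
center (and the discarded dark pixels) receive label 1. The fraction of
pixels carrying the agent-associated labels is the agent percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, ValidationError


@dataclass
class RrParams:
    """Tunables of the RR method (all in 8-bit intensity units).

    ``th`` is the pass-1 labeling similarity threshold; when left ``None`` it
    defaults to ``dth``, keeping a single intensity scale for both merging
    and labeling.
    """

    zth: int = 10
    dth: float = 16.0
    qlevels: int = 64
    th: float | None = None

    def __post_init__(self):
        if not (0 <= self.zth < 255):
            raise ValidationError("zth must lie in [0, 255)")
        if self.dth <= 0:
            raise ValidationError("dth must be positive")
        if not (8 <= self.qlevels <= 256):
            raise ValidationError("qlevels must lie in [8, 256]")

    @property
    def labeling_threshold(self) -> float:
        return self.dth if self.th is None else self.th


@dataclass
class PeakCenters:
    """Merged histogram-peak cluster centers."""

    centers: np.ndarray       # strictly increasing intensity values
    th: float                 # peak-acceptance threshold (mean nonzero bin count)
    histogram: np.ndarray     # the 256-bin histogram the peaks came from
    fallback: bool = False    # True when no peak cleared th and the global max was used


@dataclass
class AgentConcentrationImage:
    """Total labeling of a plane by nearest centers, plus the agent share."""

    labels: np.ndarray                   # H x W ints >= 1
    counts: dict[int, int]               # per-label pixel counts
    agent_percent: float = 0.0
    log: list[str] = field(default_factory=list)


def quantize_discard(plane: np.ndarray, params: RrParams) -> tuple[np.ndarray, np.ndarray]:
    """Quantize to ``qlevels`` uniform bins, discarding pixels darker than zth.

    Returns (quantized plane, discard mask). Each retained pixel maps to the
    rounded center of its bin; with qlevels = 256 the mapping is the identity.
    """
    p = np.asarray(plane)
    if not np.issubdtype(p.dtype, np.integer):
        p = np.clip(np.rint(p), 0, 255).astype(np.int64)
    discard = p < params.zth
    if discard.all():
        raise DegeneracyError(f"all pixels fall below zth={params.zth}")
    q = np.floor(p * params.qlevels / 256.0).astype(np.int64)
    centers = np.rint((q + 0.5) * 256.0 / params.qlevels - 0.5).astype(np.int64)
    out = np.where(discard, 0, np.clip(centers, 0, 255))
    return out, discard


def histogram256(plane: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """256-bin intensity histogram, optionally excluding masked pixels."""
    p = np.asarray(plane).ravel()
    if mask is not None:
        p = p[~np.asarray(mask).ravel()]
    return np.bincount(np.clip(p, 0, 255).astype(np.int64), minlength=256)


def find_peak_centers(histogram: np.ndarray, params: RrParams) -> PeakCenters:
    """Histogram peaks above the mean nonzero-bin count, merged within dth.

    Peaks are visited in decreasing count order; a candidate closer than dth
    to an accepted center is merged into it at the count-weighted mean
    position, and merging repeats until all pairwise gaps are >= dth. If no
    bin clears the threshold the global maximum becomes the single center
    (flagged as a fallback).
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.size != 256:
        raise ValidationError("expected a 256-bin histogram")
    nz = h[h > 0]
    if nz.size == 0:
        raise DegeneracyError("empty histogram")
    th = float(nz.mean())
    # local maxima: strictly greater than the nearest differing neighbor on
    # each side (plateaus count once, at their first bin); ends included
    padded = np.concatenate([[-1.0], h, [-1.0]])
    is_peak = np.zeros(256, dtype=bool)
    for i in range(256):
        if h[i] <= 0:
            continue
        left = padded[i]      # h[i-1] with sentinel
        right = padded[i + 2]
        j = i - 1
        while j >= 0 and h[j] == h[i]:
            j -= 1
        left = h[j] if j >= 0 else -1.0
        k = i + 1
        if k < 256 and h[k] == h[i]:
            continue  # plateau continues; credit the first bin only
        while k < 256 and h[k] == h[i]:
            k += 1
        right = h[k] if k < 256 else -1.0
        is_peak[i] = h[i] > left and h[i] > right
    cand = np.flatnonzero(is_peak & (h > th))
    fallback = False
    if cand.size == 0:
        cand = np.array([int(np.argmax(h))])
        fallback = True
    order = cand[np.argsort(-h[cand], kind="stable")]
    accepted: list[float] = []
    weights: list[float] = []
    for c in order:
        pos, w = float(c), float(h[c])
        if accepted:
            gaps = np.abs(np.asarray(accepted) - pos)
            j = int(np.argmin(gaps))
            if gaps[j] < params.dth:
                tot = weights[j] + w
                accepted[j] = (accepted[j] * weights[j] + pos * w) / tot
                weights[j] = tot
                continue
        accepted.append(pos)
        weights.append(w)
    # merging may have drawn accepted centers together; repeat until stable
    while len(accepted) > 1:
        arr = np.asarray(accepted)
        order2 = np.argsort(arr)
        gaps = np.diff(arr[order2])
        if gaps.min() >= params.dth:
            break
        j = int(np.argmin(gaps))
        a, b = order2[j], order2[j + 1]
        tot = weights[a] + weights[b]
        merged = (accepted[a] * weights[a] + accepted[b] * weights[b]) / tot
        for idx in sorted((a, b), reverse=True):
            del accepted[idx], weights[idx]
        accepted.append(merged)
        weights.append(tot)
    centers = np.sort(np.asarray(accepted))
    return PeakCenters(centers=centers, th=th, histogram=h.astype(np.int64),
                       fallback=fallback)


def label_by_centers(plane: np.ndarray, centers: PeakCenters,
                     params: RrParams,
                     discard_mask: np.ndarray | None = None) -> AgentConcentrationImage:
    """Label every pixel by its nearest center; the labeling is total.

    Pass 1 labels pixels within the similarity threshold of their nearest
    center; pass 2 raises the threshold to the largest minimum-center
    distance among still-unlabeled pixels and repeats. Anything left (and any
    discarded dark pixel) gets label 1. Equidistant pixels break toward the
    lower center index.
    """
    if centers.centers.size < 1:
        raise ValidationError("need at least one center")
    p = np.asarray(plane, dtype=np.float64)
    c = centers.centers
    log: list[str] = []
    dist = np.abs(p[..., None] - c)            # H x W x k
    nearest = np.argmin(dist, axis=-1)         # ties -> lower index
    mindist = np.take_along_axis(dist, nearest[..., None], axis=-1)[..., 0]
    th = params.labeling_threshold
    labels = np.where(mindist <= th, nearest + 1, 0)
    unlabeled = labels == 0
    if unlabeled.any():
        th2 = float(mindist[unlabeled].max())
        log.append(f"raised similarity threshold {th} -> {th2} for "
                   f"{int(unlabeled.sum())} unlabeled pixel(s)")
        labels = np.where(mindist <= th2, nearest + 1, 0)
    if (labels == 0).any():  # degenerate; guaranteed total anyway
        labels[labels == 0] = 1
        log.append("residual unlabeled pixels assigned label 1")
    if discard_mask is not None:
        labels = np.where(discard_mask, 1, labels)
    values, counts = np.unique(labels, return_counts=True)
    return AgentConcentrationImage(
        labels=labels.astype(np.int64),
        counts={int(v): int(n) for v, n in zip(values, counts)},
        log=log)


def agent_percentage(img: AgentConcentrationImage, agent_labels) -> float:
    """Share (in %) of pixels carrying any of the agent-associated labels."""
    agent_labels = set(int(v) for v in agent_labels)
    if not agent_labels:
        raise ValidationError("agent_labels must be nonempty")
    present = set(img.counts)
    unknown = agent_labels - present
    if unknown:
        raise ValidationError(f"label(s) {sorted(unknown)} not present in the image")
    total = img.labels.size
    hit = sum(img.counts[v] for v in agent_labels)
    return 100.0 * hit / total


@dataclass
class RrSegmentation:
    """Bundle returned by the high-level RR segmentation."""

    image: AgentConcentrationImage
    centers: PeakCenters
    raw_histogram: np.ndarray
    quantized_histogram: np.ndarray
    agent_percent: float


def segment_rr(plane: np.ndarray, params: RrParams | None = None) -> RrSegmentation:
    """Run the full RR chain on an 8-bit intensity plane.

    Peaks are found on the quantized histogram (the raw one is reported too);
    the agent percentage covers every non-background label (label >= 2), with
    label 1 — the darkest center plus discarded dark pixels — as background.
    """
    params = params or RrParams()
    q, discard = quantize_discard(plane, params)
    raw_hist = histogram256(plane)
    q_hist = histogram256(q, mask=discard)
    centers = find_peak_centers(q_hist, params)
    img = label_by_centers(q, centers, params, discard_mask=discard)
    agent = [v for v in img.counts if v >= 2]
    pct = agent_percentage(img, agent) if agent else 0.0
    img.agent_percent = pct
    return RrSegmentation(image=img, centers=centers, raw_histogram=raw_hist,
                          quantized_histogram=q_hist, agent_percent=pct)
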
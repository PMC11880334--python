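"""ACICA summary statistics, channel unmixing, and fuzzy C-means segmentation.

The segmentation proceeds in two conceptual parts:

1. an optional blind-source unmixing of the (L, u, v) channel data under the
   linear mixing model X = A S, solved by whitening plus fixed-point
   negentropy maximization (FastICA);
2. fuzzy C-means (FCM) clustering of luminance values, followed by summary
   statistics over the resulting regions: per-region mean intensities g(ii),
   squared differences of adjacent region means ("region PDF"), the mean of
   the cluster centers g_bar, and the dispersion sum((g(ii) - g_bar)^2) —
   referred to here as the agent-contrast-concentration (ACC) dispersion.

A separate pixelwise difference map |I(i,j) - I(i+1,j+1)| over diagonal
neighbors is also provided; the literature uses "PDF" for both quantities, so
both are implemented under distinct names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import DegeneracyError, ValidationError
from .io import LabelImage


@dataclass
class IcaModel:
    """Result of blind-source unmixing of k channel planes."""

    mixing: np.ndarray     # k x k, A
    unmixing: np.ndarray   # k x k, W = A^-1 (pseudo-inverse)
    sources: np.ndarray    # k x n, recovered components
    observed: np.ndarray   # k x n, the (centered) input
    mean: np.ndarray       # k, channel means removed before fitting
    converged: bool = True


@dataclass
class ClusterModel:
    """A fitted fuzzy C-means model on scalar intensities."""

    ncluster: int
    centers: np.ndarray          # sorted ascending
    memberships: np.ndarray      # n x ncluster, rows sum to 1
    fuzzifier: float
    objective_trace: np.ndarray  # nonincreasing
    values: np.ndarray           # the clustered intensities (flattened)


@dataclass
class AcicaSummary:
    """Region-level contrast summary: g, region PDF, g_bar, ACC dispersion."""

    g: np.ndarray            # per-region mean intensities
    region_pdf: np.ndarray   # squared adjacent differences of g
    gbar: float              # mean of the cluster centers
    ica: float               # sum((g - gbar)^2), the ACC dispersion


def unmix_components(planes: np.ndarray, seed: int = 0) -> IcaModel:
    """Blind-source unmixing of k flattened channel planes (k in {2, 3}).

    Channels are centered internally; components are returned in decreasing
    non-Gaussianity (|excess kurtosis|), each sign-fixed so its skewness is
    nonnegative. Rank-deficient inputs raise a degeneracy error naming the
    dependent channel; Gaussian-only sources leave the fixed-point iteration
    without a stable solution, which is reported via ``converged=False``.
    """
    X = np.asarray(planes, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] not in (2, 3):
        raise ValidationError(f"planes must be k x n with k in {{2,3}}, got {X.shape}")
    k, n = X.shape
    if n < 100:
        raise ValidationError(f"need at least 100 samples, got {n}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[-1] < 1e-10 * max(sv[0], 1.0):
        # name the channel that is (closest to) a combination of the others
        resid = np.empty(k)
        for i in range(k):
            others = np.delete(Xc, i, axis=0)
            coef, *_ = np.linalg.lstsq(others.T, Xc[i], rcond=None)
            resid[i] = np.linalg.norm(Xc[i] - coef @ others)
        dep = int(np.argmin(resid))
        raise DegeneracyError(f"channel {dep} is linearly dependent on the others")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(n_components=k, whiten="unit-variance", fun="logcosh",
                      max_iter=500, tol=1e-6, random_state=seed)
        S = ica.fit_transform(Xc.T).T   # k x n
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # order by decreasing non-Gaussianity, fix signs to nonnegative skewness
    def _m(s, p):
        z = (s - s.mean()) / max(s.std(), 1e-300)
        return float((z ** p).mean())
    kurt = [abs(_m(s, 4) - 3.0) for s in S]
    if max(kurt) < 0.2:
        # all components near-Gaussian: the rotation is unidentifiable even
        # if the fixed point nominally converged
        converged = False
    order = np.argsort([-k for k in kurt])
    S = S[order]
    A = ica.mixing_[:, order]
    for i in range(k):
        if _m(S[i], 3) < 0:
            S[i] = -S[i]
            A[:, i] = -A[:, i]
    W = np.linalg.pinv(A)
    return IcaModel(mixing=A, unmixing=W, sources=S, observed=Xc,
                    mean=mean, converged=converged)


def pixel_pdf(plane: np.ndarray) -> np.ndarray:
    """Pixelwise difference map |I(i,j) - I(i+1,j+1)| over diagonal neighbors.

    Output shape (H-1, W-1); transposing the plane transposes the map.
    """
    p = np.asarray(plane, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
        raise ValidationError("plane must be 2-D with H, W >= 2")
    return np.abs(p[:-1, :-1] - p[1:, 1:])


def region_averages(plane: np.ndarray, labels: LabelImage | np.ndarray,
                    ncluster: int | None = None) -> np.ndarray:
    """Mean intensity g(ii) over the pixels of each region ii in 1..ncluster."""
    p = np.asarray(plane, dtype=np.float64)
    lab = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
    if p.shape != lab.shape:
        raise ValidationError("plane and labels must share one shape")
    if ncluster is None:
        ncluster = int(lab.max())
    g = np.empty(ncluster)
    for ii in range(1, ncluster + 1):
        sel = lab == ii
        if not sel.any():
            raise DegeneracyError(f"region {ii} is empty")
        g[ii - 1] = p[sel].mean()
    return g


def acica_summary(g: np.ndarray, centers: np.ndarray) -> AcicaSummary:
    """Region-level summary: region PDF, center mean g_bar, ACC dispersion."""
    g = np.asarray(g, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if g.size < 1:
        raise ValidationError("g must have at least one region")
    region_pdf = np.diff(g) ** 2
    gbar = float(centers.mean())
    ica = float(((g - gbar) ** 2).sum())
    return AcicaSummary(g=g, region_pdf=region_pdf, gbar=gbar, ica=ica)


def _init_centers(values: np.ndarray, ncluster: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on intensities: spread initial centers out."""
    centers = [values[rng.integers(values.size)]]
    for _ in range(1, ncluster):
        d2 = np.min([(values - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total == 0:
            # remaining mass identical; pick any distinct value if available
            pool = np.setdiff1d(np.unique(values), np.asarray(centers))
            centers.append(pool[0] if pool.size else values[0])
            continue
        centers.append(values[rng.choice(values.size, p=d2 / total)])
    return np.asarray(centers, dtype=np.float64)


def _memberships(x: np.ndarray, centers: np.ndarray, expo: float) -> np.ndarray:
    """Bezdek membership matrix; points on a center get full membership there."""
    d = np.abs(x[:, None] - centers[None, :])
    zero = d < 1e-300
    d_safe = np.where(zero, 1.0, d)
    inv = d_safe ** (-expo)
    u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


def fcm_cluster(values: np.ndarray, ncluster: int, m: float = 2.0,
                tol: float = 1e-5, max_iter: int = 300, seed: int = 0) -> ClusterModel:
    """Fuzzy C-means on scalar intensities (Bezdek iteration).

    Memberships u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)); centers are the
    u^m-weighted means. Iterates until the largest center shift drops below
    ``tol`` or ``max_iter`` is reached. Centers are returned sorted ascending
    with membership columns reordered to match. A point coinciding with a
    center gets full membership there (shared equally if several coincide).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    ndistinct = np.unique(x).size
    if ncluster < 1 or ncluster > ndistinct:
        raise ValidationError(
            f"ncluster={ncluster} exceeds the {ndistinct} distinct value(s)")
    rng = np.random.default_rng(seed)
    centers = _init_centers(x, ncluster, rng)
    expo = 2.0 / (m - 1.0)
    trace = []
    for _ in range(max_iter):
        u = _memberships(x, centers, expo)
        um = u ** m
        d = np.abs(x[:, None] - centers[None, :])
        trace.append(float((um * d ** 2).sum()))
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            u = _memberships(x, centers, expo)
            d = np.abs(x[:, None] - centers[None, :])
            trace.append(float((u ** m * d ** 2).sum()))
            break
    order = np.argsort(centers)
    u = _memberships(x, centers[order], expo)
    return ClusterModel(ncluster=ncluster, centers=centers[order], memberships=u,
                        fuzzifier=m, objective_trace=np.asarray(trace), values=x)


def assign_levels(model: ClusterModel, shape: tuple[int, int]) -> LabelImage:
    """Per-pixel argmax membership -> labels 1..ncluster in ascending-center
    order. Exact ties break toward the lower label."""
    labels = np.argmax(model.memberships, axis=1) + 1  # argmax takes first max: low label
    return LabelImage(labels=labels.reshape(shape).astype(np.int64))


@dataclass
class AcicaSegmentation:
    """Bundle returned by the high-level ACICA segmentation."""

    labels: LabelImage
    cluster: ClusterModel
    summary: AcicaSummary
    pdf_map: np.ndarray
    ica_model: IcaModel | None = None
    log: list[str] = field(default_factory=list)


def segment_acica(luv, ncluster: int = 4, m: float = 2.0, tol: float = 1e-5,
                  max_iter: int = 300, seed: int = 0,
                  use_unmixing: bool = False) -> AcicaSegmentation:
    """Cluster the L plane into ``ncluster`` intensity levels and summarize.

    With ``use_unmixing`` the (L, u, v) channels are first unmixed and the
    most non-Gaussian component is clustered instead of L directly.
    """
    plane = luv.L
    ica_model = None
    log = []
    if use_unmixing:
        X = np.stack([luv.L.ravel(), luv.u.ravel(), luv.v.ravel()])
        ica_model = unmix_components(X, seed=seed)
        plane = ica_model.sources[0].reshape(luv.L.shape)
        log.append("clustering leading unmixed component instead of L")
    model = fcm_cluster(plane.ravel(), ncluster, m=m, tol=tol,
                        max_iter=max_iter, seed=seed)
    labels = assign_levels(model, plane.shape)
    g = region_averages(plane, labels, ncluster=ncluster)
    summary = acica_summary(g, model.centers)
    pdf_map = pixel_pdf(plane)
    log.append(f"centers={np.round(model.centers, 3).tolist()} "
               f"gbar={summary.gbar:.3f} acc={summary.ica:.3f}")
    return AcicaSegmentation(labels=labels, cluster=model, summary=summary,
                             pdf_map=pdf_map, ica_model=ica_model, log=log)
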
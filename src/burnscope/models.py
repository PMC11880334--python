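"""Burn-depth classifiers: dataset handling, augmentation, three architectures.

Three small classifiers cover the three standard families:

* CNN — three 3x3 convolution blocks (32/64/128 filters, ReLU, 2x2 max-pool,
  dropout 0.25), a 128-neuron dense layer and a 3-way softmax, consuming the
  stacked (L, u, v) planes;
* FNN — a plain dense stack on the 10-value GLCM texture feature vector;
* RNN — a tanh recurrence h_t = tanh(W_hh h_{t-1} + W_xh x_t + b_h) over the
  rows of the downsampled L plane, classified from the final hidden state.

All three are implemented directly on numpy with a shared layer/optimizer
engine so that training is fully seeded and byte-reproducible in
single-threaded runs. Training minimizes categorical cross-entropy with
adaptive-moment gradient descent (Adam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold

from .color import rgb_to_luv
from .errors import TrainingError, ValidationError
from .io import RgbImage
from .texture import feature_vector

# ---------------------------------------------------------------------------
# dataset splitting


@dataclass
class DatasetSplit:
    """Stratified train/validation/test index partition."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` with |alloc - quota| < 1."""
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_split(labels, fractions=(0.70, 0.15, 0.15), seed: int = 42) -> DatasetSplit:
    """Stratified split with deterministic rounding.

    Overall sizes: train = floor(f_train * n), validation = round-half-up
    (f_val * n), test = remainder — e.g. 63/14/13 at n = 90. Per-class counts
    stay within one item of exact proportionality (largest-remainder
    allocation inside each tier).
    """
    y = np.asarray(labels)
    n = y.size
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValidationError("fractions must be nonnegative and sum to 1")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValidationError("stratification needs at least 3 items per class")
    # epsilon guards against float artifacts (0.70 * 90 = 62.999...)
    n_train = int(np.floor(fractions[0] * n + 1e-9))
    n_val = int(np.floor(fractions[1] * n + 0.5 + 1e-9))
    rng = np.random.default_rng(seed)
    per_class = {c: rng.permutation(np.flatnonzero(y == c)) for c in classes}
    train_alloc = _largest_remainder(counts * n_train / n, n_train)
    remaining = counts - train_alloc
    val_alloc = _largest_remainder(counts * n_val / n, n_val)
    val_alloc = np.minimum(val_alloc, remaining)
    short = n_val - val_alloc.sum()
    if short > 0:  # rare cap spill-over; hand out where room remains
        room = remaining - val_alloc
        order = np.argsort(-room, kind="stable")
        for i in order:
            take = min(short, room[i])
            val_alloc[i] += take
            short -= take
            if short == 0:
                break
    train, val, test = [], [], []
    for i, c in enumerate(classes):
        idx = per_class[c]
        a, b = train_alloc[i], train_alloc[i] + val_alloc[i]
        train.append(idx[:a])
        val.append(idx[a:b])
        test.append(idx[b:])
    return DatasetSplit(train=np.sort(np.concatenate(train)),
                        val=np.sort(np.concatenate(val)),
                        test=np.sort(np.concatenate(test)),
                        fractions=tuple(fractions), seed=seed)


def kfold_split(labels, k: int = 5, seed: int = 42) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions; every item tests exactly once."""
    y = np.asarray(labels)
    if k > y.size:
        raise ValidationError(f"k={k} exceeds the {y.size} items")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(y.size), y)]


# ---------------------------------------------------------------------------
# augmentation


def augment(image: np.ndarray, rng: np.random.Generator,
            rotation: float = 15.0, brightness: float = 0.20,
            zoom: float = 0.10, clip: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """One random augmentation draw: rotate, flip, brightness, zoom.

    Rotation angle ~ U(-rotation, rotation) degrees with reflective fill;
    horizontal and vertical flips each with probability 1/2; brightness
    factor ~ U(1-brightness, 1+brightness) with clipping; zoom factor
    ~ U(1-zoom, 1+zoom) with center crop/reflective pad back to shape.
    The degenerate draw (angle 0, no flips, factors 1) is the identity.
    """
    x = np.asarray(image, dtype=np.float64)
    angle = rng.uniform(-rotation, rotation)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    factor = rng.uniform(1.0 - brightness, 1.0 + brightness)
    zf = rng.uniform(1.0 - zoom, 1.0 + zoom)
    if angle != 0.0:
        x = ndimage.rotate(x, angle, axes=(1, 0), reshape=False,
                           mode="reflect", order=1)
    if flip_h:
        x = x[:, ::-1]
    if flip_v:
        x = x[::-1, :]
    if factor != 1.0:
        x = np.clip(x * factor, *clip)
    if zf != 1.0:
        H, W = x.shape[:2]
        zoomed = ndimage.zoom(x, (zf, zf) + (1,) * (x.ndim - 2), order=1)
        h, w = zoomed.shape[:2]
        if h >= H:
            r0, c0 = (h - H) // 2, (w - W) // 2
            x = zoomed[r0:r0 + H, c0:c0 + W]
        else:
            pr, pc = H - h, W - w
            pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)) \
                + ((0, 0),) * (x.ndim - 2)
            x = np.pad(zoomed, pad, mode="reflect")
    return np.ascontiguousarray(x)


# ---------------------------------------------------------------------------
# layer engine


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_crossentropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean negative log-likelihood of one-hot targets under probabilities p."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValidationError(f"shape mismatch {y.shape} vs {p.shape}")
    p = np.clip(p, 1e-12, 1.0)
    return float(-(y * np.log(p)).sum() / y.shape[0])


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, nin, nout, rng):
        super().__init__()
        self.params = {"W": rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin),
                       "b": np.zeros(nout)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(_Layer):
    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(_Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv3x3(_Layer):
    """3x3 same-padding convolution via im2col, stride 1."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        fan_in = cin * 9
        self.params = {"W": rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in),
                       "b": np.zeros(cout)}
        self.cin, self.cout = cin, cout

    def _im2col(self, x):
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (N, C, H, W, 3, 3) -> (N, H*W, C*9)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * W, C * 9)

    def forward(self, x, train=False, rng=None):
        N, C, H, W = x.shape
        self._xshape = x.shape
        self._col = self._im2col(x)
        out = self._col @ self.params["W"] + self.params["b"]
        return out.reshape(N, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g):
        N, C, H, W = self._xshape
        gcol_out = g.transpose(0, 2, 3, 1).reshape(N, H * W, self.cout)
        self.grads = {
            "W": np.einsum("npf,npo->fo", self._col, gcol_out),
            "b": gcol_out.sum(axis=(0, 1)),
        }
        gcol = gcol_out @ self.params["W"].T      # (N, H*W, C*9)
        gcol = gcol.reshape(N, H, W, C, 3, 3)
        gx = np.zeros((N, C, H + 2, W + 2))
        for di in range(3):
            for dj in range(3):
                gx[:, :, di:di + H, dj:dj + W] += gcol[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, 1:-1, 1:-1]


class MaxPool2(_Layer):
    def forward(self, x, train=False, rng=None):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # break ties so each window backpropagates through exactly one cell
        flat = self._mask.reshape(N, C, H // 2, W // 2, 4)
        first = np.argmax(flat, axis=-1)
        sel = np.zeros_like(flat)
        np.put_along_axis(sel, first[..., None], 1.0, axis=-1)
        self._mask = sel.reshape(self._mask.shape)
        self._xshape = x.shape
        return out

    def backward(self, g):
        N, C, H, W = self._xshape
        gx = self._mask * g[:, :, :, None, :, None]
        return gx.reshape(N, C, H, W)


class Sequential:
    """Feed-forward stack producing class logits."""

    def __init__(self, layers, n_classes: int):
        self.layers = layers
        self.n_classes = n_classes
        self.preproc = None   # optional input standardizer fitted at training

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def predict_proba(self, x):
        if self.preproc is not None:
            x = self.preproc(x)
        return softmax(self.forward(x, train=False))

    def predict(self, x):
        return np.argmax(self.predict_proba(x), axis=1)


class RnnClassifier:
    """Vanilla tanh recurrence over row sequences, softmax on the last state."""

    def __init__(self, n_features: int, hidden: int, n_classes: int, rng):
        s = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wxh": rng.standard_normal((n_features, hidden)) * np.sqrt(1.0 / n_features),
            "Whh": rng.standard_normal((hidden, hidden)) * s,
            "bh": np.zeros(hidden),
            "Why": rng.standard_normal((hidden, n_classes)) * s,
            "by": np.zeros(n_classes),
        }
        self.grads = {}
        self.hidden = hidden
        self.n_classes = n_classes
        self.preproc = None

    def forward(self, x, train=False, rng=None):
        N, T, F = x.shape
        self._x = x
        self._h = np.zeros((T + 1, N, self.hidden))
        for t in range(T):
            self._h[t + 1] = np.tanh(x[:, t] @ self.params["Wxh"]
                                     + self._h[t] @ self.params["Whh"]
                                     + self.params["bh"])
        return self._h[-1] @ self.params["Why"] + self.params["by"]

    def backward(self, g):
        x, h = self._x, self._h
        N, T, F = x.shape
        p = self.params
        gr = {k: np.zeros_like(v) for k, v in p.items()}
        gr["Why"] = h[-1].T @ g
        gr["by"] = g.sum(axis=0)
        gh = g @ p["Why"].T
        for t in range(T - 1, -1, -1):
            gz = gh * (1.0 - h[t + 1] ** 2)
            gr["Wxh"] += x[:, t].T @ gz
            gr["Whh"] += h[t].T @ gz
            gr["bh"] += gz.sum(axis=0)
            gh = gz @ p["Whh"].T
        self.grads = gr
        return None

    def parameters(self):
        for name in self.params:
            yield self, name

    def predict_proba(self, x):
        if self.preproc is not None:
            x = self.preproc(x)
        return softmax(self.forward(x, train=False))

    def predict(self, x):
        return np.argmax(self.predict_proba(x), axis=1)

    @property
    def layers(self):  # uniform interface for weight hashing
        return [self]


@dataclass
class ModelSpec:
    """Architecture description; shapes are validated at build time."""

    kind: str = "cnn"                 # cnn | fnn | rnn
    n_classes: int = 3
    input_size: int = 224             # cnn: square input side (divisible by 8)
    feature_dim: int = 10             # fnn: texture feature dimension
    fnn_hidden: tuple[int, ...] = (32, 16)
    rnn_steps: int = 32               # rnn: rows of the downsampled L plane
    rnn_features: int = 32
    rnn_hidden: int = 64
    conv_filters: tuple[int, ...] = (32, 64, 128)
    dense_units: int = 128
    dropout: float = 0.25


def build_model(spec: ModelSpec, seed: int = 0):
    """Construct a trainable model; forward on a batch yields N x C logits."""
    rng = np.random.default_rng(seed)
    if spec.kind == "cnn":
        if spec.input_size % 8 != 0:
            raise ValidationError("cnn input size must be divisible by 8 (three 2x2 pools)")
        layers, cin = [], 3
        for cout in spec.conv_filters:
            layers += [Conv3x3(cin, cout, rng), ReLU(), MaxPool2(), Dropout(spec.dropout)]
            cin = cout
        side = spec.input_size // 2 ** len(spec.conv_filters)
        layers += [Flatten(), Dense(cin * side * side, spec.dense_units, rng), ReLU(),
                   Dense(spec.dense_units, spec.n_classes, rng)]
        return Sequential(layers, spec.n_classes)
    if spec.kind == "fnn":
        layers, nin = [], spec.feature_dim
        for nh in spec.fnn_hidden:
            layers += [Dense(nin, nh, rng), ReLU()]
            nin = nh
        layers.append(Dense(nin, spec.n_classes, rng))
        return Sequential(layers, spec.n_classes)
    if spec.kind == "rnn":
        return RnnClassifier(spec.rnn_features, spec.rnn_hidden, spec.n_classes, rng)
    raise ValidationError(f"unknown model kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 42
    augment: bool = True
    rotation: float = 15.0     # degrees
    brightness: float = 0.20
    zoom: float = 0.10


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)


class _Adam:
    def __init__(self, lr):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m, self.v, self.t = {}, {}, 0

    def step(self, model):
        self.t += 1
        for layer, name in model.parameters():
            key = (id(layer), name)
            g = layer.grads[name]
            self.m[key] = self.b1 * self.m.get(key, 0.0) + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v.get(key, 0.0) + (1 - self.b2) * g * g
            mh = self.m[key] / (1 - self.b1 ** self.t)
            vh = self.v[key] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train(model, X: np.ndarray, y: np.ndarray,
          X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          cfg: TrainConfig | None = None, augment_fn=None,
          standardize: bool = False) -> History:
    """Seeded minibatch training with per-epoch shuffling.

    ``augment_fn(sample, rng)`` is applied to each training sample each epoch
    (image-input models only). ``standardize`` fits a feature standardizer on
    the training set and stores it on the model. Raises on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    if len(X) == 0:
        raise ValidationError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        model.preproc = lambda a, mu=mu, sd=sd: (a - mu) / sd
    Xp = model.preproc(X) if model.preproc is not None else X
    Y = one_hot(y, model.n_classes)
    opt = _Adam(cfg.learning_rate)
    hist = History()
    n = len(Xp)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = Xp[idx]
            if augment_fn is not None and cfg.augment:
                xb = np.stack([augment_fn(s, rng) for s in xb])
            yb = Y[idx]
            logits = model.forward(xb, train=True, rng=rng)
            p = softmax(logits)
            loss = categorical_crossentropy(yb, p)
            if not np.isfinite(loss):
                raise TrainingError(epoch + 1)
            losses.append(loss)
            hits += int((np.argmax(p, axis=1) == np.argmax(yb, axis=1)).sum())
            model.backward((p - yb) / len(idx))
            opt.step(model)
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(hits / n)
        if X_val is not None and len(X_val):
            pv = model.predict_proba(X_val)
            hist.val_loss.append(categorical_crossentropy(one_hot(y_val, model.n_classes), pv))
            hist.val_acc.append(float((np.argmax(pv, axis=1) == y_val).mean()))
    return hist


def weights_hash(model) -> str:
    """Order-stable hash of all parameters (reproducibility checks)."""
    import hashlib
    h = hashlib.sha256()
    for layer, name in model.parameters():
        h.update(name.encode())
        h.update(np.ascontiguousarray(layer.params[name]).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalMetrics:
    confusion: np.ndarray            # C x C, rows = truth, cols = prediction
    accuracy: float
    precision: np.ndarray            # per class
    recall: np.ndarray
    f1: np.ndarray
    macro: dict[str, float]
    weighted: dict[str, float]
    absent_classes: list[int]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": {
                str(c): {"precision": float(self.precision[c]),
                         "recall": float(self.recall[c]),
                         "f1": float(self.f1[c])}
                for c in range(len(self.precision))},
            "macro": self.macro,
            "weighted": self.weighted,
        }


def metrics_from_confusion(cm: np.ndarray) -> EvalMetrics:
    """All derived metrics from a confusion matrix (rows = truth)."""
    cm = np.asarray(cm, dtype=np.int64)
    C = cm.shape[0]
    n = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1).astype(np.float64)
    predicted = cm.sum(axis=0).astype(np.float64)
    absent = [c for c in range(C) if support[c] == 0 and predicted[c] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    w = support / n if n else support
    macro = {"precision": float(precision.mean()), "recall": float(recall.mean()),
             "f1": float(f1.mean())}
    weighted = {"precision": float(precision @ w), "recall": float(recall @ w),
                "f1": float(f1 @ w)}
    return EvalMetrics(confusion=cm, accuracy=float(tp.sum() / n) if n else 0.0,
                       precision=precision, recall=recall, f1=f1,
                       macro=macro, weighted=weighted, absent_classes=absent)


def evaluate(model, X: np.ndarray, y: np.ndarray,
             n_classes: int | None = None) -> EvalMetrics:
    """Confusion matrix and derived metrics of the model on labeled items."""
    if len(X) == 0:
        raise ValidationError("empty evaluation set")
    C = n_classes or model.n_classes
    pred = model.predict(X)
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (np.asarray(y, dtype=int), pred), 1)
    return metrics_from_confusion(cm)


def collapse_binary(y: np.ndarray, deep_class: int = 2) -> np.ndarray:
    """Two-class view of burn severity: 0 = up-to-dermal, 1 = deep."""
    return (np.asarray(y) == deep_class).astype(np.int64)


# ---------------------------------------------------------------------------
# input preparation for each architecture


def luv_stack(image: RgbImage, size: int) -> np.ndarray:
    """(3, size, size) channel stack of the Luv planes, each scaled to ~[0, 1]."""
    luv = rgb_to_luv(image)
    planes = np.stack([luv.L / 100.0,
                       (luv.u + 134.0) / 354.0,
                       (luv.v + 140.0) / 262.0], axis=-1)
    small = resize(planes, (size, size), order=1, anti_aliasing=True)
    return np.ascontiguousarray(small.transpose(2, 0, 1))


def rnn_sequence(image: RgbImage, steps: int = 32, features: int = 32) -> np.ndarray:
    """(steps, features) row sequence of the downsampled L plane in [0, 1]."""
    luv = rgb_to_luv(image)
    return resize(luv.L / 100.0, (steps, features), order=1, anti_aliasing=True)


def texture_features(images: list[RgbImage], levels: int = 8,
                     distance: int = 1) -> np.ndarray:
    """(N, 10) texture feature matrix (Luv conversion + GLCM per image)."""
    return np.stack([feature_vector(rgb_to_luv(img), levels=levels,
                                    distance=distance).values for img in images])


def prepare_inputs(images: list[RgbImage], kind: str, input_size: int = 32,
                   levels: int = 8, distance: int = 1) -> np.ndarray:
    """Architecture-appropriate input arrays for a list of images."""
    if kind == "cnn":
        return np.stack([luv_stack(img, input_size) for img in images])
    if kind == "fnn":
        return texture_features(images, levels=levels, distance=distance)
    if kind == "rnn":
        return np.stack([rnn_sequence(img) for img in images])
    raise ValidationError(f"unknown model kind {kind!r}")


def _cnn_augment(sample: np.ndarray, rng: np.random.Generator,
                 cfg: TrainConfig) -> np.ndarray:
    """Augment a (C, H, W) Luv channel stack through the (H, W, C) form.

    Brightness jitter touches only the luminance channel: the chroma
    channels are offset-encoded, so scaling them would shift hue instead of
    brightness and push training inputs off the test distribution.
    """
    img = sample.transpose(1, 2, 0)
    out = augment(img, rng, rotation=cfg.rotation, brightness=0.0,
                  zoom=cfg.zoom, clip=(0.0, 1.0))
    factor = rng.uniform(1.0 - cfg.brightness, 1.0 + cfg.brightness)
    out = out.copy()
    out[..., 0] = np.clip(out[..., 0] * factor, 0.0, 1.0)
    return out.transpose(2, 0, 1)


def train_classifier(images: list[RgbImage], labels: np.ndarray, kind: str,
                     cfg: TrainConfig | None = None, input_size: int = 32,
                     fractions=(0.70, 0.15, 0.15)):
    """End-to-end convenience: split, prepare, train and test one classifier.

    Labels may be any integers; they are densely re-encoded internally.
    Returns (model, split, history, test metrics).
    """
    cfg = cfg or TrainConfig()
    classes = np.unique(labels)
    y = np.searchsorted(classes, labels)
    split = stratified_split(y, fractions=fractions, seed=cfg.seed)
    X = prepare_inputs(images, kind, input_size=input_size)
    spec = ModelSpec(kind=kind, n_classes=len(classes), input_size=input_size)
    model = build_model(spec, seed=cfg.seed)
    augment_fn = (lambda s, rng: _cnn_augment(s, rng, cfg)) if kind == "cnn" else None
    hist = train(model, X[split.train], y[split.train],
                 X[split.val], y[split.val], cfg=cfg,
                 augment_fn=augment_fn, standardize=(kind == "fnn"))
    metrics = evaluate(model, X[split.test], y[split.test])
    return model, split, hist, metrics
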
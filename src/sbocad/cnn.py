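"""Small convolutional network for lesion/background patch classification.

The segmenter is a compact CNN trained in two phases: gradient descent on a
softmax cross-entropy loss with an L2 weight penalty, optionally followed by
a satin-bowerbird refinement of the flattened weight vector against the mean
squared output error — the population step can hop out of the local minimum
the gradient settled in.  Segmentation labels every pixel by sliding a patch
window over the image, classifying each patch, and averaging the per-pixel
lesion votes.

Everything (convolution, pooling, dropout, backprop) is implemented directly
on numpy arrays in NHWC layout; gradients are exact and are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import sbo as sbo_mod

__all__ = [
    "conv_forward",
    "relu",
    "max_pool",
    "softmax",
    "cross_entropy_loss",
    "output_mse",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "PatchNet",
    "TrainConfig",
    "backprop_gradients",
    "gd_train",
    "sbo_refine",
    "sbo_hyperparameter_search",
    "segment",
    "sample_patches",
    "patch_architecture",
    "table_architecture",
]


# ---------------------------------------------------------------------------
# functional primitives


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int = 1):
    """(N,H,W,C) -> (N, Ho*Wo, kh*kw*C) patch matrix plus output dims."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    v = v[:, ::stride, ::stride]            # (N, Ho, Wo, C, kh, kw)
    v = v.transpose(0, 1, 2, 4, 5, 3)       # (N, Ho, Wo, kh, kw, C)
    n, ho, wo = v.shape[:3]
    cols = np.ascontiguousarray(v).reshape(n, ho * wo, kh * kw * x.shape[3])
    return cols, (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of _im2col for stride 1: scatter-add column grads back."""
    n, h, w, c = x_shape
    ho, wo = h - kh + 1, w - kw + 1
    dx = np.zeros(x_shape)
    d = dcols.reshape(n, ho, wo, kh, kw, c)
    for a in range(kh):
        for b in range(kw):
            dx[:, a:a + ho, b:b + wo, :] += d[:, :, :, a, b, :]
    return dx


def conv_forward(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray,
                 stride: int = 1) -> np.ndarray:
    """Valid cross-correlation of an NHWC batch with (kh, kw, Cin, F) kernels."""
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim != 4 or kernels.ndim != 4:
        raise ValueError("expected NHWC input and (kh, kw, Cin, F) kernels")
    kh, kw, cin, f = kernels.shape
    if cin != x.shape[3]:
        raise ValueError("kernel channel count does not match input")
    if kh > x.shape[1] or kw > x.shape[2]:
        raise ValueError("kernel larger than input")
    cols, (ho, wo) = _im2col(x, kh, kw, stride)
    out = cols @ kernels.reshape(kh * kw * cin, f) + biases
    return out.reshape(x.shape[0], ho, wo, f)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(x, 0)


def max_pool(x: np.ndarray, pool: int = 2, stride: int = 2) -> np.ndarray:
    """Block-maximum downsampling; odd remainders are edge-replicated."""
    layer = MaxPool2D(pool, stride)
    return layer.forward(np.asarray(x, dtype=float))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(z: np.ndarray, d: np.ndarray,
                       weights: list[np.ndarray] | None = None,
                       theta: float = 0.0, reduction: str = "sum") -> float:
    """Cross entropy of softmax outputs z against one-hot targets d.

    L = sum_samples sum_classes -d log z  +  (theta/2) * sum W^2, the penalty
    running over connection weights only (never biases).  Probabilities that
    are exactly zero at a target class are clamped at 1e-12.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    data = -(d * np.log(np.clip(z, 1e-12, None))).sum()
    if reduction == "mean":
        data /= z.shape[0]
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    penalty = 0.0
    if weights and theta:
        penalty = 0.5 * theta * sum(float((w ** 2).sum()) for w in weights)
    return float(data + penalty)


def output_mse(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean (over samples) of the squared output error summed over classes.

    E = (1/Ns) * sum_i sum_j (d_ji - o_ji)^2 — the objective handed to the
    bowerbird refinement phase.
    """
    o = np.asarray(outputs, dtype=float)
    d = np.asarray(targets, dtype=float)
    return float(((d - o) ** 2).sum() / o.shape[0])


# ---------------------------------------------------------------------------
# layers


class Conv2D:
    """Valid convolution layer, stride 1, He-initialized."""

    def __init__(self, kh: int, kw: int, cin: int, filters: int,
                 rng: np.random.Generator):
        fan_in = kh * kw * cin
        self.W = rng.standard_normal((kh, kw, cin, filters)) * math.sqrt(2.0 / fan_in)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    has_weights = True

    def forward(self, x, train=False, rng=None):
        kh, kw, cin, f = self.W.shape
        cols, (ho, wo) = _im2col(x, kh, kw)
        out = cols @ self.W.reshape(-1, f) + self.b
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(x.shape[0], ho, wo, f)

    def backward(self, g):
        cols, x_shape, (ho, wo) = self._cache
        kh, kw, cin, f = self.W.shape
        gm = g.reshape(g.shape[0], ho * wo, f)
        self.dW = np.einsum("npk,npf->kf", cols, gm).reshape(self.W.shape)
        self.db = gm.sum(axis=(0, 1))
        dcols = gm @ self.W.reshape(-1, f).T
        return _col2im(dcols, x_shape, kh, kw)


class ReLU:
    has_weights = False

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2D:
    """Max pooling with replicate padding when dims do not divide evenly."""

    has_weights = False

    def __init__(self, pool: int = 2, stride: int | None = None):
        self.pool = pool
        self.stride = stride if stride is not None else pool

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        p, s = self.pool, self.stride
        ho = max(1, math.ceil((h - p) / s) + 1)
        wo = max(1, math.ceil((w - p) / s) + 1)
        pad_h = (ho - 1) * s + p - h
        pad_w = (wo - 1) * s + p - w
        xp = np.pad(x, ((0, 0), (0, pad_h), (0, pad_w), (0, 0)), mode="edge")
        win = np.lib.stride_tricks.sliding_window_view(xp, (p, p), axis=(1, 2))
        win = win[:, ::s, ::s]                      # (N, Ho, Wo, C, p, p)
        flat = win.reshape(n, ho, wo, c, p * p)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, arg)
        return out

    def backward(self, g):
        x_shape, xp_shape, arg = self._cache
        n, h, w, c = x_shape
        p, s = self.pool, self.stride
        ho, wo = arg.shape[1:3]
        dxp = np.zeros(xp_shape)
        ni, hi, wi, ci = np.meshgrid(np.arange(n), np.arange(ho), np.arange(wo),
                                     np.arange(c), indexing="ij")
        rows = hi * s + arg // p
        colz = wi * s + arg % p
        np.add.at(dxp, (ni, rows, colz, ci), g)
        # fold gradients that landed in the replicated pad back onto the edge
        if xp_shape[1] > h:
            dxp[:, h - 1, :, :] += dxp[:, h:, :, :].sum(axis=1)
        if xp_shape[2] > w:
            dxp[:, :, w - 1, :] += dxp[:, :, w:, :].sum(axis=2)
        return dxp[:, :h, :w, :]


class Dropout:
    """Inverted dropout: drop with probability p at train time, identity at eval."""

    has_weights = False

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten:
    has_weights = False

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense:
    has_weights = True

    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = rng.standard_normal((nin, nout)) * math.sqrt(2.0 / nin)
        self.b = np.zeros(nout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T


# ---------------------------------------------------------------------------
# network


class PatchNet:
    """An ordered stack of layers ending in logits for a softmax classifier."""

    def __init__(self, layers: list, input_shape: tuple[int, int, int]):
        self.layers = layers
        self.input_shape = tuple(input_shape)  # (H, W, C)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    # -- parameter housing: every weight/bias tensor flattens to one vector

    def _weight_layers(self):
        return [l for l in self.layers if l.has_weights]

    def weight_tensors(self) -> list[np.ndarray]:
        return [l.W for l in self._weight_layers()]

    def get_params(self) -> np.ndarray:
        parts = []
        for l in self._weight_layers():
            parts.append(l.W.ravel())
            parts.append(l.b.ravel())
        return np.concatenate(parts)

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        i = 0
        for l in self._weight_layers():
            for name in ("W", "b"):
                arr = getattr(l, name)
                n = arr.size
                setattr(l, name, vec[i:i + n].reshape(arr.shape).copy())
                i += n
        if i != vec.size:
            raise ValueError("parameter vector length mismatch")

    @property
    def n_params(self) -> int:
        return sum(l.W.size + l.b.size for l in self._weight_layers())

    def loss_and_gradients(self, x: np.ndarray, d: np.ndarray, theta: float = 0.0,
                           train: bool = False,
                           rng: np.random.Generator | None = None,
                           reduction: str = "sum"):
        """Forward + backward pass; returns (loss, flat gradient vector)."""
        logits = self.forward(x, train=train, rng=rng)
        z = softmax(logits)
        loss = cross_entropy_loss(z, d, self.weight_tensors(), theta, reduction)
        g = z - d
        if reduction == "mean":
            g = g / x.shape[0]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        parts = []
        for l in self._weight_layers():
            dW = l.dW + theta * l.W  # d/dW of the (theta/2) sum W^2 penalty
            parts.append(dW.ravel())
            parts.append(l.db.ravel())
        return loss, np.concatenate(parts)


def backprop_gradients(net: PatchNet, x: np.ndarray, d: np.ndarray,
                       theta: float = 0.0, reduction: str = "sum") -> np.ndarray:
    """Exact gradient of the penalized cross-entropy w.r.t. every parameter."""
    _, grad = net.loss_and_gradients(x, d, theta=theta, train=False,
                                     reduction=reduction)
    return grad


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Gradient-descent phase settings plus the optional SBO refinement.

    ``iterations`` defaults to the full-scale budget of 8000; desk-scale
    callers pass far fewer.  ``theta`` is the L2 weight-penalty coefficient.
    """

    learning_rate: float = 0.1
    iterations: int = 8000
    theta: float = 1e-4
    dropout_active: bool = True
    seed: int = 0
    sbo: sbo_mod.SBOConfig | None = None
    sbo_delta: float = 0.5
    loss_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


def gd_train(net: PatchNet, x: np.ndarray, d: np.ndarray,
             config: TrainConfig) -> list[float]:
    """Full-batch gradient descent on the mean penalized cross-entropy.

    Returns the per-iteration loss history; aborts if the loss diverges.
    """
    rng = np.random.default_rng(config.seed)
    history = []
    for it in range(config.iterations):
        loss, grad = net.loss_and_gradients(
            x, d, theta=config.theta, train=config.dropout_active, rng=rng,
            reduction="mean")
        if not math.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}")
        net.set_params(net.get_params() - config.learning_rate * grad)
        history.append(loss)
    config.loss_history = history
    return history


def sbo_refine(net: PatchNet, x: np.ndarray, d: np.ndarray,
               sbo_config: sbo_mod.SBOConfig | None = None,
               delta: float = 0.5) -> sbo_mod.OptimizationResult:
    """Population refinement of the flattened weights against the MSE error.

    The search box is centered on the current parameter vector with half
    width ``delta``; the current vector seeds the population, so elitism
    guarantees the refined error never exceeds the starting error.
    """
    theta0 = net.get_params()
    if sbo_config is None:
        sbo_config = sbo_mod.SBOConfig(
            population_size=200, max_iterations=10,
            lower_bounds=theta0 - delta, upper_bounds=theta0 + delta)
    if sbo_config.max_iterations == 0:
        return sbo_mod.OptimizationResult(
            best_position=theta0, seed=sbo_config.seed,
            best_objective=output_mse(net.predict_proba(x), d), history=[])

    def objective(vec):
        net.set_params(vec)
        return output_mse(net.predict_proba(x), d)
    result = sbo_mod.optimize(objective, sbo_config, initial=theta0)
    net.set_params(result.best_position)
    return result


def sbo_hyperparameter_search(x: np.ndarray, d: np.ndarray, patch_size: int,
                              window_max: int | None = None,
                              sbo_config: sbo_mod.SBOConfig | None = None,
                              gd_iters: int = 40, learning_rate: float = 0.2,
                              seed: int = 0):
    """SBO over integer sliding-window (kernel) sizes in [2, window_max].

    Each candidate encodes the two conv kernel sizes; the objective is the
    MSE output error after a short gradient-descent burn-in.  The lower
    bound 2 is the smallest window that still pools; the upper bound keeps
    every window inside the input patch.
    """
    if window_max is None:
        window_max = max(2, patch_size // 2)
    window_max = min(window_max, patch_size - 1)
    if sbo_config is None:
        sbo_config = sbo_mod.SBOConfig(
            population_size=6, max_iterations=4, seed=seed,
            lower_bounds=np.array([2.0, 2.0]),
            upper_bounds=np.array([float(window_max), float(window_max)]))

    def objective(vec):
        k1, k2 = (int(round(v)) for v in np.clip(vec, 2, window_max))
        h1 = math.ceil((patch_size - k1 + 1) / 2)
        if h1 <= 2:
            return math.inf  # first window leaves no room for the second
        k2 = min(k2, h1 - 1)
        net = patch_architecture(patch_size=patch_size, channels=x.shape[3],
                                 kernels=(k1, k2), seed=seed)
        cfg = TrainConfig(learning_rate=learning_rate, iterations=gd_iters,
                          theta=0.0, dropout_active=False, seed=seed)
        gd_train(net, x, d, cfg)
        return output_mse(net.predict_proba(x), d)

    result = sbo_mod.optimize(objective, sbo_config)
    best = tuple(int(round(v)) for v in np.clip(result.best_position, 2, window_max))
    return best, result


# ---------------------------------------------------------------------------
# architectures


def patch_architecture(patch_size: int = 32, channels: int = 1,
                       filters: tuple[int, int] = (8, 16),
                       kernels: tuple[int, int] = (3, 3),
                       dense: int = 32, classes: int = 2,
                       dropout: float = 0.0, seed: int = 0) -> PatchNet:
    """Desk-scale two-conv patch classifier: conv-relu-pool twice, then FC."""
    rng = np.random.default_rng(seed)
    h = patch_size
    layers: list = []
    cin = channels
    for f, k in zip(filters, kernels):
        if k >= h:
            raise ValueError("kernel does not fit the remaining spatial extent")
        layers += [Conv2D(k, k, cin, f, rng), ReLU(), MaxPool2D(2, 2)]
        h = math.ceil((h - k + 1) / 2)
        cin = f
    if dropout:
        layers.append(Dropout(dropout))
    layers.append(Flatten())
    layers += [Dense(h * h * cin, dense, rng), ReLU(), Dense(dense, classes, rng)]
    return PatchNet(layers, (patch_size, patch_size, channels))


def table_architecture(classes: int = 2, filters: tuple[int, int, int] = (8, 16, 32),
                       dense: int = 256, dropout: float = 0.6,
                       seed: int = 0) -> PatchNet:
    """Full-image geometry: 256x256x3 input, 11/7/3 conv kernels, 2x2 pools,
    dropout 0.6, a 256-wide fully connected layer and an M-way softmax head."""
    rng = np.random.default_rng(seed)
    layers: list = [
        Conv2D(11, 11, 3, filters[0], rng), ReLU(), MaxPool2D(2, 2),
        Conv2D(7, 7, filters[0], filters[1], rng), ReLU(), MaxPool2D(2, 2),
        Conv2D(3, 3, filters[1], filters[2], rng), ReLU(),
        Dropout(dropout), Flatten(),
    ]
    h = 256
    h = math.ceil((h - 11 + 1) / 2)   # conv 11 + pool
    h = math.ceil((h - 7 + 1) / 2)    # conv 7 + pool
    h = h - 3 + 1                     # conv 3
    layers += [Dense(h * h * filters[2], dense, rng), ReLU(),
               Dense(dense, classes, rng)]
    return PatchNet(layers, (256, 256, 3))


# ---------------------------------------------------------------------------
# segmentation


def sample_patches(images: list[np.ndarray], masks: list[np.ndarray],
                   patch_size: int, n_per_image: int,
                   rng: np.random.Generator):
    """Draw class-balanced training patches; a patch's label is its center pixel.

    Returns (X, d) with X of shape (N, p, p, 1) and d one-hot (N, 2) where
    class 1 is lesion.
    """
    half = patch_size // 2
    xs, ys = [], []
    for img, mask in zip(images, masks):
        if img.ndim == 3:
            raise ValueError("sample_patches expects grayscale images")
        h, w = img.shape
        valid = np.zeros((h, w), bool)
        valid[half:h - (patch_size - half) + 1, half:w - (patch_size - half) + 1] = True
        for cls in (0, 1):
            cand = np.flatnonzero(valid & (mask.astype(bool) == bool(cls)))
            if cand.size == 0:
                continue
            pick = rng.choice(cand, size=min(n_per_image // 2, cand.size),
                              replace=False)
            for flat in pick:
                r, c = divmod(int(flat), w)
                xs.append(img[r - half:r - half + patch_size,
                              c - half:c - half + patch_size])
                ys.append(cls)
    x = np.asarray(xs, dtype=float)[..., None]
    y = np.asarray(ys, dtype=int)
    d = np.zeros((y.size, 2))
    d[np.arange(y.size), y] = 1.0
    return x, d


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    keep = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(keep)


def segment(image: np.ndarray, net: PatchNet, patch_size: int = 32,
            stride: int = 8, threshold: float = 0.5,
            postprocess: bool = True, batch: int = 4096) -> np.ndarray:
    """Sliding-window patch voting: each patch's lesion probability is spread
    over its footprint, per-pixel votes are averaged and thresholded, and the
    largest connected component is kept with holes filled."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment expects a grayscale image")
    h, w = image.shape
    if h < patch_size or w < patch_size:
        raise ValueError("image smaller than the patch window")
    rows = sorted(set(range(0, h - patch_size + 1, stride)) | {h - patch_size})
    cols = sorted(set(range(0, w - patch_size + 1, stride)) | {w - patch_size})
    coords = [(r, c) for r in rows for c in cols]
    patches = np.empty((len(coords), patch_size, patch_size, 1))
    for i, (r, c) in enumerate(coords):
        patches[i, :, :, 0] = image[r:r + patch_size, c:c + patch_size]
    probs = np.empty(len(coords))
    for start in range(0, len(coords), batch):
        chunk = patches[start:start + batch]
        probs[start:start + len(chunk)] = net.predict_proba(chunk)[:, 1]
    votes = np.zeros((h, w))
    counts = np.zeros((h, w))
    for (r, c), p in zip(coords, probs):
        votes[r:r + patch_size, c:c + patch_size] += p
        counts[r:r + patch_size, c:c + patch_size] += 1.0
    mask = (votes / counts) >= threshold
    if postprocess and mask.any():
        mask = _largest_component(mask)
    return mask
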
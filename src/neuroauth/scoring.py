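"""Class balancing (SMOTE) and per-modality match-score estimation.

Two scorers mirror the two signal modalities:

* a small convolutional network for the sparse 20 x 20 ERP feature maps —
  conv(6 maps, kernel 5) -> maxpool 2 -> conv(12 maps, kernel 3) ->
  maxpool 2 -> flatten (108) -> fully connected 2-unit output; sigmoid
  activations, mean-squared-error loss, plain SGD with learning rate 1,
  batch size 100, 500 epochs (the classic sigmoid/MSE ConvNet recipe that
  those hyperparameters belong to);
* a back-propagation network for the 20-dimensional blink vectors —
  20 -> 5 -> 5 -> 5 -> 2, sigmoid activations, full-batch gradient descent.

Both emit the user-class output unit as a match score in [0, 1]. Inputs are
standardized with statistics frozen from the training set; all weight
initialization and batch shuffling is seeded, so training is deterministic.

SMOTE synthesizes minority-class samples along segments from each sample to
one of its K nearest neighbours: x_new = x + rand(0,1) * (x~ - x). The
variant with the segment direction reversed (x - x~), which extrapolates
instead of interpolating, is available as ``as_printed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.neighbors import NearestNeighbors

# ---------------------------------------------------------------- SMOTE


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    magnification: int = 14   # synthetic samples per original; 100 -> 1500
    seed: int = 0
    as_printed: bool = False  # reversed segment direction (extrapolation)

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.magnification < 0:
            raise ValueError("magnification must be >= 0")


def smote_oversample(minority: np.ndarray, cfg: SmoteConfig) -> np.ndarray:
    """Return the originals plus ``len(minority) * magnification`` synthetic
    vectors generated along nearest-neighbour segments.

    ``minority`` is an (n, d) array with n > k_neighbors.
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2:
        raise ValueError("minority must be an (n, d) array")
    n = X.shape[0]
    if n <= cfg.k_neighbors:
        raise ValueError(
            f"minority size {n} must exceed k_neighbors {cfg.k_neighbors}")
    if cfg.magnification == 0:
        return X.copy()
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X)
    _, nbrs = nn.kneighbors(X)          # column 0 is the sample itself
    nbrs = nbrs[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    out = [X]
    for _ in range(cfg.magnification):
        pick = nbrs[np.arange(n), rng.integers(0, cfg.k_neighbors, size=n)]
        u = rng.uniform(0.0, 1.0, size=(n, 1))
        direction = (X - X[pick]) if cfg.as_printed else (X[pick] - X)
        out.append(X + u * direction)
    return np.vstack(out)


# ------------------------------------------------------- shared net pieces


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    r = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-r, r, size=shape)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((labels.size, 2))
    y[np.arange(labels.size), labels.astype(int)] = 1.0
    return y


# ------------------------------------------------------------------- CNN


@dataclass(frozen=True)
class CnnSpec:
    input_size: int = 20
    conv1_maps: int = 6
    conv1_kernel: int = 5
    pool1: int = 2
    conv2_maps: int = 12
    conv2_kernel: int = 3
    pool2: int = 2
    n_outputs: int = 2
    learning_rate: float = 1.0
    batch_size: int = 100
    epochs: int = 500
    seed: int = 0

    @property
    def flatten_size(self) -> int:
        """Units entering the fully connected layer, derived from the
        architecture: ((20-5+1)/2 - 3 + 1)/2 = 3, and 3*3*12 = 108."""
        s = self.input_size
        s = (s - self.conv1_kernel + 1) // self.pool1
        s = (s - self.conv2_kernel + 1) // self.pool2
        return s * s * self.conv2_maps


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho, Wo, C*k*k) patch matrix (valid windows)."""
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # B,C,Ho,Wo,k,k
    b, c, ho, wo = v.shape[:4]
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, c * k * k)


def _conv_forward(x, W, b):
    """Valid convolution. W: (F, C, k, k); returns (B, F, Ho, Wo)."""
    f, c, k, _ = W.shape
    col = _im2col(x, k)
    out = col @ W.reshape(f, -1).T + b
    return out.transpose(0, 3, 1, 2), col


def _conv_backward(dz, col, W, x_shape):
    """Gradients of a valid convolution; dz: (B, F, Ho, Wo)."""
    f, c, k, _ = W.shape
    b_, _, ho, wo = dz.shape
    dzf = dz.transpose(0, 2, 3, 1).reshape(-1, f)
    dW = (dzf.T @ col.reshape(-1, c * k * k)).reshape(W.shape)
    db = dzf.sum(axis=0)
    dcol = (dzf @ W.reshape(f, -1)).reshape(b_, ho, wo, c, k, k)
    dx = np.zeros(x_shape)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + ho, j:j + wo] += dcol[:, :, :, :, i, j].transpose(
                0, 3, 1, 2)
    return dW, db, dx


def _pool_forward(x, s):
    b, f, h, w = x.shape
    win = x.reshape(b, f, h // s, s, w // s, s)
    out = win.max(axis=(3, 5))
    mask = win == out[:, :, :, None, :, None]
    # ties share the gradient equally
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return out, mask


def _pool_backward(dz, mask, s):
    b, f, h2, _, w2, _ = mask.shape
    d = mask * dz[:, :, :, None, :, None]
    return d.reshape(b, f, h2 * s, w2 * s)


class CnnScorer:
    """Trained convolutional match scorer for 20 x 20 ERP feature maps."""

    def __init__(self, spec: CnnSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        k1, k2 = spec.conv1_kernel, spec.conv2_kernel
        self.W1 = _glorot(rng, (spec.conv1_maps, 1, k1, k1),
                          k1 * k1, spec.conv1_maps * k1 * k1)
        self.b1 = np.zeros(spec.conv1_maps)
        self.W2 = _glorot(rng, (spec.conv2_maps, spec.conv1_maps, k2, k2),
                          spec.conv1_maps * k2 * k2,
                          spec.conv2_maps * k2 * k2)
        self.b2 = np.zeros(spec.conv2_maps)
        self.W3 = _glorot(rng, (spec.flatten_size, spec.n_outputs),
                          spec.flatten_size, spec.n_outputs)
        self.b3 = np.zeros(spec.n_outputs)
        self.mu = 0.0
        self.sigma = 1.0
        self._rng = rng

    # forward ---------------------------------------------------------
    def _forward(self, x):
        z1, col1 = _conv_forward(x, self.W1, self.b1)
        a1 = _sigmoid(z1)
        p1, m1 = _pool_forward(a1, self.spec.pool1)
        z2, col2 = _conv_forward(p1, self.W2, self.b2)
        a2 = _sigmoid(z2)
        p2, m2 = _pool_forward(a2, self.spec.pool2)
        flat = p2.reshape(x.shape[0], -1)
        out = _sigmoid(flat @ self.W3 + self.b3)
        cache = (x, col1, a1, m1, p1, col2, a2, m2, p2, flat, out)
        return out, cache

    def _backward(self, y, cache):
        x, col1, a1, m1, p1, col2, a2, m2, p2, flat, out = cache
        b = x.shape[0]
        dout = (out - y) / b * out * (1.0 - out)
        dW3 = flat.T @ dout
        db3 = dout.sum(axis=0)
        dflat = dout @ self.W3.T
        dp2 = dflat.reshape(p2.shape)
        da2 = _pool_backward(dp2, m2, self.spec.pool2)
        dz2 = da2 * a2 * (1.0 - a2)
        dW2, db2, dp1 = _conv_backward(dz2, col2, self.W2, p1.shape)
        da1 = _pool_backward(dp1, m1, self.spec.pool1)
        dz1 = da1 * a1 * (1.0 - a1)
        dW1, db1, _ = _conv_backward(dz1, col1, self.W1, x.shape)
        return dW1, db1, dW2, db2, dW3, db3

    def fit(self, maps: np.ndarray, labels: np.ndarray) -> "CnnScorer":
        X = np.asarray(maps, dtype=float)
        y = np.asarray(labels)
        if X.ndim != 3 or X.shape[1:] != (self.spec.input_size,) * 2:
            raise ValueError("maps must be (n, 20, 20)")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.mu = float(X.mean())
        self.sigma = float(X.std()) or 1.0
        Xs = ((X - self.mu) / self.sigma)[:, None, :, :]
        Y = _one_hot(y)
        lr = self.spec.learning_rate
        n = X.shape[0]
        bs = min(self.spec.batch_size, n)
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            for s in range(0, n, bs):
                idx = order[s:s + bs]
                _, cache = self._forward(Xs[idx])
                dW1, db1, dW2, db2, dW3, db3 = self._backward(Y[idx], cache)
                self.W1 -= lr * dW1
                self.b1 -= lr * db1
                self.W2 -= lr * dW2
                self.b2 -= lr * db2
                self.W3 -= lr * dW3
                self.b3 -= lr * db3
        return self

    def score_batch(self, maps: np.ndarray) -> np.ndarray:
        X = np.asarray(maps, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.spec.input_size,) * 2:
            raise ValueError("maps must be 20 x 20")
        Xs = ((X - self.mu) / self.sigma)[:, None, :, :]
        out, _ = self._forward(Xs)
        return out[:, 1]

    def score(self, feature_map: np.ndarray) -> float:
        return float(self.score_batch(np.asarray(feature_map)[None])[0])


def train_cnn(maps, labels, spec: CnnSpec) -> CnnScorer:
    """Train a CNN scorer on 20 x 20 maps with 0 (imposter) / 1 (user)
    labels; deterministic for a fixed spec seed."""
    arr = np.asarray([m.expanded if hasattr(m, "expanded") else m
                      for m in maps], dtype=float)
    return CnnScorer(spec).fit(arr, np.asarray(labels))


def score_cnn(scorer: CnnScorer, feature_map) -> float:
    m = feature_map.expanded if hasattr(feature_map, "expanded") \
        else feature_map
    return scorer.score(np.asarray(m))


# -------------------------------------------------------------------- NN


@dataclass(frozen=True)
class NnSpec:
    n_inputs: int = 20
    hidden: tuple[int, ...] = (5, 5, 5)
    n_outputs: int = 2
    learning_rate: float = 0.1
    epochs: int = 2000
    seed: int = 0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, self.n_outputs)


class NnScorer:
    """Fully connected sigmoid network for 20-dim blink feature vectors."""

    def __init__(self, spec: NnSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        sizes = spec.layer_sizes
        self.weights = [_glorot(rng, (a, b), a, b)
                        for a, b in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(b) for b in sizes[1:]]
        self.mu = np.zeros(spec.n_inputs)
        self.sigma = np.ones(spec.n_inputs)

    def _forward(self, x):
        acts = [x]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def fit(self, vectors: np.ndarray, labels: np.ndarray) -> "NnScorer":
        X = np.asarray(vectors, dtype=float)
        y = np.asarray(labels)
        if X.ndim != 2 or X.shape[1] != self.spec.n_inputs:
            raise ValueError(f"vectors must be (n, {self.spec.n_inputs})")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.mu = X.mean(axis=0)
        self.sigma = X.std(axis=0)
        self.sigma[self.sigma == 0] = 1.0
        Xs = (X - self.mu) / self.sigma
        Y = _one_hot(y)
        lr = self.spec.learning_rate
        n = X.shape[0]
        for _ in range(self.spec.epochs):
            acts = self._forward(Xs)
            out = acts[-1]
            delta = (out - Y) / n * out * (1.0 - out)
            for layer in range(len(self.weights) - 1, -1, -1):
                a_prev = acts[layer]
                dW = a_prev.T @ delta
                db = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ self.weights[layer].T
                             * a_prev * (1.0 - a_prev))
                self.weights[layer] -= lr * dW
                self.biases[layer] -= lr * db
        return self

    def score_batch(self, vectors: np.ndarray) -> np.ndarray:
        X = np.asarray(vectors, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != self.spec.n_inputs:
            raise ValueError(f"vectors must have {self.spec.n_inputs} entries")
        Xs = (X - self.mu) / self.sigma
        return self._forward(Xs)[-1][:, 1]

    def score(self, vector: np.ndarray) -> float:
        return float(self.score_batch(np.asarray(vector)[None])[0])


def train_nn(vectors, labels, spec: NnSpec) -> NnScorer:
    arr = np.asarray([v.values if hasattr(v, "values") else v
                      for v in vectors], dtype=float)
    return NnScorer(spec).fit(arr, np.asarray(labels))


def score_nn(scorer: NnScorer, vector) -> float:
    v = vector.values if hasattr(vector, "values") else vector
    return scorer.score(np.asarray(v))
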
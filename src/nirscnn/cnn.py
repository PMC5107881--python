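"""From-scratch two-class 1D convolutional network with momentum-SGD backprop.

The network is the minimal architecture used for per-channel fNIRS group
classification: a single convolution stage (K kernels of length m, valid
convolution, stride 1), an elementwise activation, one max-pooling stage,
and a fully connected softmax output layer with C=2 neurons whose outputs
are the class probabilities.  Training minimizes softmax cross-entropy
(one-hot mean squared error selectable) by full-batch gradient descent
with classical momentum:

    v <- momentum * v - lr * grad;   w <- w + v

The default activation is the logistic sigmoid.  A rectifier is
selectable, but with the very high default momentum (0.998) the
transient weight oscillations routinely drive every rectifier unit into
the flat region at once; the gradient then vanishes identically and the
network degenerates to a bias-only classifier of the class priors.  The
sigmoid has no such absorbing state and trains reliably here.

Everything is plain numpy and deterministic given the initialization seed
and the data order.  Intermediate activations of the forward pass are
cached and exposed because the learned kernels and pooled activations are
themselves analysis outputs (see :mod:`nirscnn.interpret`).

Default hyperparameters: learning rate 0.05, momentum 0.998, kernel
1 x 10 stride 1, pool 1 x 2, K = 9 kernels, 5000 epochs.  The printed
pooling stride of the reference configuration (stride 1) is inconsistent
with its own stated halving of a 200-element series to 100; the default
here is stride 2 (= pool length, non-overlapping), with the stride
exposed in :class:`CNNConfig` for anyone who wants the overlapping
variant.
"""

from __future__ import annotations

import base64
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._kernels import pool2
from .data import FeatureSeries

__all__ = [
    "CNNConfig",
    "CNNModel",
    "conv_output_len",
    "pool_output_len",
    "convolve",
    "activate",
    "max_pool",
    "dense_forward",
    "softmax",
    "forward",
    "loss",
    "init_model",
    "gradients",
    "train",
    "predict",
    "save_model",
    "load_model",
]

N_CLASSES = 2


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the per-channel classifier."""

    learning_rate: float = 0.05
    momentum: float = 0.998
    kernel_len: int = 10
    kernel_stride: int = 1
    pool_len: int = 2
    pool_stride: int = 2
    n_kernels: int = 9
    epochs: int = 5000
    activation: str = "sigmoid"
    loss: str = "cross_entropy"
    batch_mode: str = "full"
    init_seed: int = 0
    max_restarts: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        for name in ("kernel_len", "kernel_stride", "pool_len", "pool_stride",
                     "n_kernels", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.batch_mode not in ("full", "per_sample"):
            raise ValueError("batch_mode must be 'full' or 'per_sample'")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be >= 0")

    def fast(self, epochs: int = 200) -> "CNNConfig":
        """Reduced-epoch profile for quick runs; all else unchanged."""
        return replace(self, epochs=epochs)


def _relu(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def _relu_grad_from_output(y: np.ndarray) -> np.ndarray:
    # y > 0 iff u > 0; the rectifier derivative at exactly 0 is taken as 0
    return (y > 0).astype(float)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    # tanh form: overflow-free and markedly faster than exp-based variants
    return 0.5 * (1.0 + np.tanh(0.5 * u))


def _sigmoid_grad_from_output(y: np.ndarray) -> np.ndarray:
    return y * (1.0 - y)


# activation -> (f, derivative expressed through the activation output)
_ACTIVATIONS = {
    "relu": (_relu, _relu_grad_from_output),
    "sigmoid": (_sigmoid, _sigmoid_grad_from_output),
}


def conv_output_len(n: int, kernel_len: int, stride: int = 1) -> int:
    """Length of a valid (unpadded) convolution output."""
    if n < kernel_len:
        raise ValueError(f"input length {n} shorter than kernel length {kernel_len}")
    return (n - kernel_len) // stride + 1


def pool_output_len(length: int, pool_len: int, stride: int) -> int:
    if length < pool_len:
        raise ValueError(f"feature map length {length} shorter than pool length {pool_len}")
    return (length - pool_len) // stride + 1


@dataclass
class CNNModel:
    """Learnable parameters plus configuration of one channel's classifier.

    ``kernels`` has shape (K, m); ``dense_w`` has shape (2, K * P) where P
    is the pooled length, flattened kernel-major so the slice
    ``dense_w[:, k*P:(k+1)*P]`` holds the weights fed by kernel k's pooled
    units; ``dense_b`` has shape (2,).
    """

    kernels: np.ndarray
    dense_w: np.ndarray
    dense_b: np.ndarray
    config: CNNConfig
    n_features: int
    velocities: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.dense_w = np.asarray(self.dense_w, dtype=float)
        self.dense_b = np.asarray(self.dense_b, dtype=float)
        if self.kernels.shape != (self.config.n_kernels, self.config.kernel_len):
            raise ValueError("kernels shape inconsistent with config")
        if self.dense_w.shape != (N_CLASSES, self.config.n_kernels * self.pooled_len):
            raise ValueError("dense_w shape inconsistent with config/input length")
        if self.dense_b.shape != (N_CLASSES,):
            raise ValueError("dense_b must have one entry per class")

    @property
    def conv_len(self) -> int:
        return conv_output_len(self.n_features, self.config.kernel_len,
                               self.config.kernel_stride)

    @property
    def pooled_len(self) -> int:
        return pool_output_len(
            conv_output_len(self.n_features, self.config.kernel_len,
                            self.config.kernel_stride),
            self.config.pool_len,
            self.config.pool_stride,
        )


def init_model(config: CNNConfig, n_features: int,
               seed: Optional[int] = None) -> CNNModel:
    """Random fan-in-scaled uniform initialization, biases zero."""
    rng = np.random.default_rng(config.init_seed if seed is None else seed)
    k, m = config.n_kernels, config.kernel_len
    pooled = pool_output_len(
        conv_output_len(n_features, m, config.kernel_stride),
        config.pool_len, config.pool_stride,
    )
    kernels = rng.uniform(-1.0, 1.0, (k, m)) / np.sqrt(m)
    dense_w = rng.uniform(-1.0, 1.0, (N_CLASSES, k * pooled)) / np.sqrt(k * pooled)
    dense_b = np.zeros(N_CLASSES)
    return CNNModel(kernels, dense_w, dense_b, config, n_features)


# ---------------------------------------------------------------------------
# Layers (single-sample public surface)

def convolve(features: np.ndarray, kernels: np.ndarray, stride: int = 1) -> np.ndarray:
    """Valid 1-D convolution (sliding inner product, no kernel flip).

    Returns K feature maps of shape (K, (N - m)//stride + 1):
    ``out[k, i] = sum_a features[i*stride + a] * kernels[k, a]``.
    """
    x = np.asarray(features, dtype=float)
    w = np.atleast_2d(np.asarray(kernels, dtype=float))
    if x.ndim != 1:
        raise ValueError("features must be 1-D")
    conv_output_len(x.size, w.shape[1], stride)  # validates N >= m
    windows = sliding_window_view(x, w.shape[1])[::stride]
    return (windows @ w.T).T


def activate(u: np.ndarray, kind: str = "relu") -> np.ndarray:
    """Elementwise activation (``relu`` or ``sigmoid``)."""
    return _ACTIVATIONS[kind][0](np.asarray(u, dtype=float))


def max_pool(y: np.ndarray, pool_len: int = 2, pool_stride: int = 2) -> np.ndarray:
    """Max pooling along the last axis.

    Output length floor((L - pool_len)/stride) + 1; with pool_len =
    stride = 2 and even L this halves the length (a 200-element series
    pools to 100).
    """
    y = np.asarray(y, dtype=float)
    pool_output_len(y.shape[-1], pool_len, pool_stride)
    windows = sliding_window_view(y, pool_len, axis=-1)[..., ::pool_stride, :]
    return windows.max(axis=-1)


def dense_forward(pooled_flat: np.ndarray, weights: np.ndarray,
                  bias: np.ndarray) -> np.ndarray:
    """Fully connected affine layer: ``u_j = sum_i w_ji y'_i + b_j``."""
    x = np.asarray(pooled_flat, dtype=float).ravel()
    w = np.asarray(weights, dtype=float)
    b = np.asarray(bias, dtype=float)
    if w.shape[1] != x.size or w.shape[0] != b.size:
        raise ValueError(
            f"dimension mismatch: weights {w.shape}, input {x.size}, bias {b.size}"
        )
    return w @ x + b


def softmax(u: np.ndarray) -> np.ndarray:
    """Overflow-safe softmax (shift-invariant: softmax(u) = softmax(u - max u))."""
    u = np.asarray(u, dtype=float)
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def forward(model: CNNModel, features: np.ndarray | FeatureSeries
            ) -> tuple[np.ndarray, dict]:
    """Full forward pass on one sample.

    Returns ``(probabilities, cache)``; the cache holds every
    intermediate (conv pre-activations ``u_conv``, activations ``y``,
    pooled maps ``pooled`` of shape (K, P), the flattened vector, dense
    pre-activations and probabilities) for backprop and interpretation.
    """
    if isinstance(features, FeatureSeries):
        features = features.values
    x = np.asarray(features, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"feature length {x.shape} does not match model input length "
            f"({model.n_features},)"
        )
    cfg = model.config
    u_conv = convolve(x, model.kernels, cfg.kernel_stride)
    y = activate(u_conv, cfg.activation)
    pooled = max_pool(y, cfg.pool_len, cfg.pool_stride)
    flat = pooled.reshape(-1)  # kernel-major
    u_dense = dense_forward(flat, model.dense_w, model.dense_b)
    p = softmax(u_dense)
    cache = {
        "x": x, "u_conv": u_conv, "y": y, "pooled": pooled,
        "flat": flat, "u_dense": u_dense, "p": p,
    }
    return p, cache


def loss(p: np.ndarray, label: int, kind: str = "cross_entropy") -> float:
    """Per-sample loss of the predicted class probabilities.

    ``cross_entropy``: -log p[label], log argument clamped away from 0.
    ``mse``: squared error against the one-hot target, summed over classes.
    """
    p = np.asarray(p, dtype=float)
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if kind == "cross_entropy":
        return float(-np.log(max(p[label], 1e-300)) + 0.0)  # + 0.0 folds -0.0
    if kind == "mse":
        target = np.zeros(p.size)
        target[label] = 1.0
        return float(((p - target) ** 2).sum())
    raise ValueError(f"unknown loss {kind!r}")


# ---------------------------------------------------------------------------
# Batched forward/backward used by training

def _batch_forward(model: CNNModel, windows: np.ndarray) -> dict:
    """Forward pass on pre-windowed contiguous inputs of shape (S, L, m)."""
    cfg = model.config
    act, _ = _ACTIVATIONS[cfg.activation]
    S, L, m = windows.shape
    u = (windows.reshape(S * L, m) @ model.kernels.T).reshape(S, L, -1)  # (S, L, K)
    y = act(u)
    P = model.pooled_len
    fwd: dict = {"y": y}
    if cfg.pool_len == 2 and cfg.pool_stride == 2:
        # default non-overlapping width-2 pooling: a pairwise max beats argmax
        even = y[:, 0:2 * P:2]
        odd = y[:, 1:2 * P:2]
        mask = odd > even                            # tie -> first (even) position
        pooled = np.where(mask, odd, even)           # (S, P, K)
        fwd["mask"] = mask
    elif cfg.pool_stride == cfg.pool_len:
        blocks = y[:, : P * cfg.pool_len].reshape(S, P, cfg.pool_len, -1)
        arg = blocks.argmax(axis=2)                  # (S, P, K)
        pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
        fwd["arg"] = arg
    else:
        pw = sliding_window_view(y, cfg.pool_len, axis=1)[:, ::cfg.pool_stride]
        pooled = pw.max(axis=-1)                     # (S, P, K)
        fwd["arg"] = pw.argmax(axis=-1)
    flat = pooled.transpose(0, 2, 1).reshape(S, -1)  # kernel-major
    u_dense = flat @ model.dense_w.T + model.dense_b  # (S, 2)
    fwd.update(pooled=pooled, flat=flat, p=softmax(u_dense))
    return fwd


def _input_windows(X: np.ndarray, config: CNNConfig) -> np.ndarray:
    w = sliding_window_view(X, config.kernel_len, axis=1)[:, ::config.kernel_stride]
    return np.ascontiguousarray(w)


def gradients(model: CNNModel, X: np.ndarray, y_true: np.ndarray,
              windows: Optional[np.ndarray] = None
              ) -> tuple[float, dict[str, np.ndarray]]:
    """Mean loss over the batch and its analytic gradients.

    Backprop routes the pooled-layer gradient to the argmax position of
    each pooling block (first position on ties); the rectifier gradient
    at exactly 0 is taken as 0.
    """
    cfg = model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_true = np.asarray(y_true, dtype=int)
    if windows is None:
        windows = _input_windows(X, cfg)
    fwd = _batch_forward(model, windows)
    S = X.shape[0]
    P = model.pooled_len
    K = cfg.n_kernels
    probs = fwd["p"]
    onehot = np.zeros_like(probs)
    onehot[np.arange(S), y_true] = 1.0

    if cfg.loss == "cross_entropy":
        batch_loss = float(
            -np.log(np.maximum(probs[np.arange(S), y_true], 1e-300)).mean()
        )
        g_udense = (probs - onehot) / S                      # (S, 2)
    else:  # mse against one-hot, through the softmax jacobian
        batch_loss = float(((probs - onehot) ** 2).sum(axis=1).mean())
        dldp = 2.0 * (probs - onehot)
        g_udense = probs * (dldp - (dldp * probs).sum(axis=1, keepdims=True))
        g_udense /= S

    g_dense_w = g_udense.T @ fwd["flat"]
    g_dense_b = g_udense.sum(axis=0)
    g_flat = g_udense @ model.dense_w                         # (S, K*P)
    g_pooled = g_flat.reshape(S, K, P).transpose(0, 2, 1)     # (S, P, K)

    g_y = np.zeros_like(fwd["y"])                             # (S, L, K)
    if "mask" in fwd:                                         # width-2 fast path
        mask = fwd["mask"]
        g_y[:, 0:2 * P:2] = np.where(mask, 0.0, g_pooled)
        g_y[:, 1:2 * P:2] = np.where(mask, g_pooled, 0.0)
    elif cfg.pool_stride == cfg.pool_len:
        # non-overlapping blocks: scatter through a reshaped view
        view = g_y[:, : P * cfg.pool_len].reshape(S, P, cfg.pool_len, K)
        np.put_along_axis(view, fwd["arg"][:, :, None, :],
                          g_pooled[:, :, None, :], axis=2)
    else:
        arg = fwd["arg"]
        s_idx = np.arange(S)[:, None]
        k_idx = np.arange(K)[None, :]
        for c in range(P):
            np.add.at(g_y, (s_idx, c * cfg.pool_stride + arg[:, c], k_idx),
                      g_pooled[:, c])

    _, act_grad = _ACTIVATIONS[cfg.activation]
    g_uconv = g_y * act_grad(fwd["y"])                        # (S, L, K)
    L = g_uconv.shape[1]
    g_kernels = g_uconv.reshape(S * L, K).T @ windows.reshape(S * L, -1)  # (K, m)
    return batch_loss, {
        "kernels": g_kernels, "dense_w": g_dense_w, "dense_b": g_dense_b,
    }


def _as_xy(dataset: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Accept [(features, label), ...] or [FeatureSeries, ...]."""
    feats, labels = [], []
    for item in dataset:
        if isinstance(item, FeatureSeries):
            if item.label is None:
                raise ValueError(f"unlabeled FeatureSeries {item.subject!r}")
            feats.append(item.values)
            labels.append(item.label)
        else:
            f, lab = item
            feats.append(f.values if isinstance(f, FeatureSeries) else np.asarray(f, float))
            labels.append(int(lab))
    lengths = {f.shape[-1] for f in feats}
    if len(lengths) > 1:
        raise ValueError(f"feature series of unequal length: {sorted(lengths)}")
    return np.array(feats, dtype=float), np.array(labels, dtype=int)


# A stalled run: after the full epoch budget the training loss is still at
# (or above) the level of trivially predicting the class frequencies, i.e.
# the optimizer either saturated every unit (an absorbing state) or is
# still in its oscillatory transient.  Either way the returned network has
# not fit the training data and a fresh initialization is warranted.
# Partially-fit networks are not accepted: they systematically lean
# toward the majority class of the training fold, which in leave-one-out
# is the opposite of the held-out subject's class.
_STALL_LOSS = {"cross_entropy": 0.55, "mse": 0.35}


def _batch_loss(model: CNNModel, windows: np.ndarray, y: np.ndarray) -> float:
    """Mean loss of the current parameters (no gradients)."""
    fwd = _batch_forward(model, windows)
    S = y.shape[0]
    if model.config.loss == "cross_entropy":
        return float(-np.log(np.maximum(fwd["p"][np.arange(S), y], 1e-300)).mean())
    onehot = np.zeros_like(fwd["p"])
    onehot[np.arange(S), y] = 1.0
    return float(((fwd["p"] - onehot) ** 2).sum(axis=1).mean())


def _fit_once(X: np.ndarray, y: np.ndarray, windows: np.ndarray,
              config: CNNConfig, seed: int
              ) -> tuple[CNNModel, np.ndarray, dict]:
    """One full training run from a fresh initialization."""
    model = init_model(config, X.shape[1], seed=seed)
    vel = {
        "kernels": np.zeros_like(model.kernels),
        "dense_w": np.zeros_like(model.dense_w),
        "dense_b": np.zeros_like(model.dense_b),
    }
    params = {"kernels": model.kernels, "dense_w": model.dense_w,
              "dense_b": model.dense_b}
    trace = np.empty(config.epochs)
    lr, mom = config.learning_rate, config.momentum
    grads: dict = {}
    for epoch in range(config.epochs):
        if config.batch_mode == "full":
            epoch_loss, grads = gradients(model, X, y, windows=windows)
            for name, g in grads.items():
                v = vel[name]
                v *= mom
                v -= lr * g
                params[name] += v
        else:  # per-sample updates in fixed data order
            losses = []
            for s in range(X.shape[0]):
                l_s, grads = gradients(model, X[s:s + 1], y[s:s + 1],
                                       windows=windows[s:s + 1])
                losses.append(l_s)
                for name, g in grads.items():
                    v = vel[name]
                    v *= mom
                    v -= lr * g
                    params[name] += v
            epoch_loss = float(np.mean(losses))
        trace[epoch] = epoch_loss
    model.velocities = vel
    return model, trace, grads


def _stalled(final_loss: float, config: CNNConfig, attempt: int = 0) -> bool:
    if config.learning_rate == 0:
        return False  # weights cannot move; a restart would change nothing
    return bool(final_loss > _STALL_LOSS[config.loss])


def restart_seed(base_seed: int, attempt: int) -> int:
    """Derived initialization seed of restart ``attempt`` (>= 1)."""
    ss = np.random.SeedSequence([int(base_seed), int(attempt)])
    return int(ss.generate_state(1)[0] % (2**31))


def train(dataset: Sequence, config: CNNConfig = CNNConfig(),
          seed: Optional[int] = None
          ) -> tuple[CNNModel, np.ndarray]:
    """Train the classifier with momentum SGD.

    ``dataset`` is a sequence of labeled :class:`FeatureSeries` or
    ``(features, label)`` pairs containing both classes.  Returns the
    trained model and the per-epoch mean loss trace (length ``epochs``,
    loss measured before each update).

    The very high default momentum makes individual runs sensitive to
    the initialization: the transient can drive every unit into
    saturation at once (an absorbing state in which the network can only
    fit the class priors) or leave the weights still oscillating when
    the epoch budget ends.  A run whose final training loss has not
    beaten the trivial level is therefore retried from a fresh
    initialization whose seed is derived deterministically from the base
    seed, up to ``config.max_restarts`` times; the last attempt is
    returned regardless.  The whole procedure is fully deterministic
    given the seed (``config.init_seed`` unless ``seed`` overrides it)
    and the data order.
    """
    X, y = _as_xy(dataset)
    classes = set(y.tolist())
    if classes != {0, 1}:
        raise ValueError(
            f"training data must contain both classes 0 and 1, got {sorted(classes)}"
        )
    base_seed = config.init_seed if seed is None else seed
    windows = _input_windows(X, config)
    # restarts cannot help when every training sample is the same vector:
    # no network separates identical inputs, so the trivial loss is optimal
    max_restarts = 0 if bool(np.all(X == X[0])) else config.max_restarts
    for attempt in range(max_restarts + 1):
        attempt_seed = base_seed if attempt == 0 else restart_seed(base_seed, attempt)
        model, trace, _ = _fit_once(X, y, windows, config, attempt_seed)
        # judge the run by the loss of the weights actually returned: the
        # final momentum step can jump far from the last measured loss
        if not _stalled(_batch_loss(model, windows, y), config, attempt):
            break
    return model, trace


def _init_fold_params(config: CNNConfig, n_features: int, seeds: Sequence[int]
                      ) -> dict[str, np.ndarray]:
    """Stacked per-fold parameters, each fold initialized exactly like
    :func:`init_model` with its own seed."""
    models = [init_model(config, n_features, seed=s) for s in seeds]
    return {
        "kernels": np.stack([m.kernels for m in models]),
        "dense_w": np.stack([m.dense_w for m in models]),
        "dense_b": np.stack([m.dense_b for m in models]),
    }


def _train_folds_batched(
    X: np.ndarray,
    y: np.ndarray,
    config: CNNConfig,
    fold_indices: Sequence[int],
    seeds: Sequence[int],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Train one leave-one-out model per fold simultaneously.

    Fold f trains on every sample except ``fold_indices[f]``, implemented
    as a per-(fold, sample) weight of 1/(S-1) (0 for the held-out one) so
    each fold's gradient equals the plain mean over its training samples.
    All folds share the windowed input; parameters carry a leading fold
    axis and every step is a batched matmul in single precision.  Returns
    the stacked parameters and the (epochs, F) loss trace.  Fold dynamics
    are fully independent — results match per-fold :func:`train` up to
    floating-point precision and summation order.
    """
    S, n = X.shape
    F = len(fold_indices)
    cfg = config
    act, act_grad = _ACTIVATIONS[cfg.activation]
    windows = _input_windows(X, cfg)              # (S, L, m)
    L, m = windows.shape[1], windows.shape[2]
    K = cfg.n_kernels
    P = pool_output_len(L, cfg.pool_len, cfg.pool_stride)
    if cfg.pool_len != cfg.pool_stride:
        raise ValueError("batched LOOCV training requires pool_stride == pool_len")
    # single precision: the fold-batched arrays are large enough that the
    # epoch loop is memory- and exp()-bound; float32 roughly halves both.
    w2d = windows.reshape(S * L, m).astype(np.float32)
    if cfg.pool_len == 2:
        # windows under the even/odd positions of each width-2 pooling
        # block, pre-copied contiguous so backward never scatters
        w32 = w2d.reshape(S, L, m)
        w_even = np.ascontiguousarray(w32[:, 0:2 * P:2]).reshape(S * P, m)
        w_odd = np.ascontiguousarray(w32[:, 1:2 * P:2]).reshape(S * P, m)

    weights = np.full((F, S), 1.0 / (S - 1), dtype=np.float32)
    weights[np.arange(F), np.asarray(fold_indices)] = 0.0
    onehot = np.zeros((S, N_CLASSES), dtype=np.float32)
    onehot[np.arange(S), y] = 1.0

    params = _init_fold_params(cfg, n, seeds)
    params = {k: v.astype(np.float32) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    trace = np.empty((cfg.epochs, F))
    lr, mom = cfg.learning_rate, cfg.momentum
    pl = cfg.pool_len
    if pl != 2:
        g_yact = np.zeros((F, S, L, K), dtype=np.float32)

    for epoch in range(cfg.epochs):
        u = (w2d @ params["kernels"].transpose(0, 2, 1)).reshape(F, S, L, K)
        if pl == 2:
            # the activation is monotone, so pooling commutes with it:
            # pool the pre-activations, then activate only the winners
            pooled_u, mask = pool2(u, P)                  # (F, S, P, K)
            pooled = act(pooled_u)
        else:
            yact = act(u)
            blocks = yact[:, :, : P * pl].reshape(F, S, P, pl, K)
            arg = blocks.argmax(axis=3)
            pooled = np.take_along_axis(
                blocks, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        flat = pooled.transpose(0, 1, 3, 2).reshape(F, S, K * P)  # kernel-major
        u_dense = flat @ params["dense_w"].transpose(0, 2, 1) + params["dense_b"][:, None, :]
        probs = softmax(u_dense)                          # (F, S, 2)

        ce = -np.log(np.maximum(probs, np.float32(1e-30)))
        per_sample = (ce * onehot[None]).sum(axis=2) if cfg.loss == "cross_entropy" \
            else ((probs - onehot[None]) ** 2).sum(axis=2)
        trace[epoch] = (per_sample * weights).sum(axis=1)

        if cfg.loss == "cross_entropy":
            g_ud = (probs - onehot[None]) * weights[:, :, None]
        else:
            dldp = 2.0 * (probs - onehot[None])
            g_ud = probs * (dldp - (dldp * probs).sum(axis=2, keepdims=True))
            g_ud *= weights[:, :, None]
        g_dw = g_ud.transpose(0, 2, 1) @ flat             # (F, 2, K*P)
        g_db = g_ud.sum(axis=1)
        g_flat = g_ud @ params["dense_w"]                 # (F, S, K*P)
        g_pooled = g_flat.reshape(F, S, K, P).transpose(0, 1, 3, 2)
        if pl == 2:
            # max routes the gradient to the block's winning position;
            # apply the activation derivative there (from the pooled
            # activation) and accumulate the kernel gradient from the
            # even and odd positions against their pre-copied windows
            g_win = g_pooled * act_grad(pooled)
            g_even = np.where(mask, np.float32(0.0), g_win)
            g_odd = np.where(mask, g_win, np.float32(0.0))
            g_k = g_even.reshape(F, S * P, K).transpose(0, 2, 1) @ w_even
            g_k += g_odd.reshape(F, S * P, K).transpose(0, 2, 1) @ w_odd
        else:
            g_yact[...] = 0.0
            view = g_yact[:, :, : P * pl].reshape(F, S, P, pl, K)
            np.put_along_axis(view, arg[:, :, :, None, :],
                              g_pooled[:, :, :, None, :], axis=3)
            g_uconv = g_yact * act_grad(yact)
            g_k = g_uconv.reshape(F, S * L, K).transpose(0, 2, 1) @ w2d

        for name, g in (("kernels", g_k), ("dense_w", g_dw), ("dense_b", g_db)):
            v = vel[name]
            v *= mom
            v -= lr * g
            params[name] += v

    # post-update loss of the returned weights, for the stall decision
    u = (w2d @ params["kernels"].transpose(0, 2, 1)).reshape(F, S, L, K)
    if pl == 2:
        pooled = act(pool2(u, P)[0])
    else:
        blocks = act(u)[:, :, : P * pl].reshape(F, S, P, pl, K)
        pooled = blocks.max(axis=3)
    flat = pooled.transpose(0, 1, 3, 2).reshape(F, S, K * P)
    probs = softmax(flat @ params["dense_w"].transpose(0, 2, 1)
                    + params["dense_b"][:, None, :])
    if cfg.loss == "cross_entropy":
        per_sample = -np.log(np.maximum(probs[:, np.arange(S), y], np.float32(1e-30)))
    else:
        per_sample = ((probs - onehot[None]) ** 2).sum(axis=2)
    final_losses = (per_sample * weights).sum(axis=1)
    return params, trace, final_losses


def train_loocv(
    X: np.ndarray,
    y: np.ndarray,
    config: CNNConfig = CNNConfig(),
    fold_seeds: Optional[Sequence[int]] = None,
) -> list[CNNModel]:
    """Leave-one-out training: one model per sample, trained on the rest.

    Equivalent to calling :func:`train` on each fold's training set but
    executed for all folds at once (batched over a fold axis), which is
    several times faster.  ``fold_seeds`` gives each fold's
    initialization seed (default ``config.init_seed`` for all).  Stalled
    runs are restarted per fold with derived seeds exactly as in
    :func:`train`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    S = X.shape[0]
    if fold_seeds is None:
        fold_seeds = [config.init_seed] * S
    if len(fold_seeds) != S:
        raise ValueError("need one fold seed per sample")
    for f in range(S):
        if len(set(np.delete(y, f).tolist())) < 2:
            raise ValueError("every LOOCV training fold must contain both classes")

    pending = list(range(S))
    seeds = {f: int(fold_seeds[f]) for f in pending}
    done: dict[int, dict[str, np.ndarray]] = {}
    # identical training samples make restarts futile (see train())
    max_restarts = 0 if bool(np.all(X == X[0])) else config.max_restarts
    for attempt in range(max_restarts + 1):
        attempt_seeds = [
            seeds[f] if attempt == 0 else restart_seed(seeds[f], attempt)
            for f in pending
        ]
        params, trace, final_losses = _train_folds_batched(
            X, y, config, pending, attempt_seeds)
        still = []
        for i, f in enumerate(pending):
            if _stalled(final_losses[i], config, attempt) and attempt < max_restarts:
                still.append(f)
            else:
                done[f] = {k: v[i].astype(float) for k, v in params.items()}
        pending = still
        if not pending:
            break
    return [
        CNNModel(done[f]["kernels"], done[f]["dense_w"], done[f]["dense_b"],
                 config, X.shape[1])
        for f in range(S)
    ]


def predict(model: CNNModel, features: np.ndarray | FeatureSeries
            ) -> tuple[int, np.ndarray]:
    """Predicted class and probabilities; an exact tie resolves to class 0."""
    p, _ = forward(model, features)
    return (0 if p[0] >= p[1] else 1), p


# ---------------------------------------------------------------------------
# Serialization: single self-describing JSON file, bit-exact round trip.

_FORMAT = "nirscnn-model-v1"


def _array_to_json(a: np.ndarray) -> dict:
    return {
        "shape": list(a.shape),
        "b64": base64.b64encode(np.ascontiguousarray(a, dtype="<f8").tobytes()).decode(),
    }


def _array_from_json(d: dict) -> np.ndarray:
    a = np.frombuffer(base64.b64decode(d["b64"]), dtype="<f8").astype(float)
    return a.reshape(d["shape"])


def save_model(model: CNNModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "format": _FORMAT,
        "config": asdict(model.config),
        "n_features": model.n_features,
        "kernels": _array_to_json(model.kernels),
        "dense_w": _array_to_json(model.dense_w),
        "dense_b": _array_to_json(model.dense_b),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def load_model(path: str | Path) -> CNNModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _FORMAT:
        raise ValueError(f"not a {_FORMAT} file: {path}")
    return CNNModel(
        kernels=_array_from_json(doc["kernels"]),
        dense_w=_array_from_json(doc["dense_w"]),
        dense_b=_array_from_json(doc["dense_b"]),
        config=CNNConfig(**doc["config"]),
        n_features=int(doc["n_features"]),
    )
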
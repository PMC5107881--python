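"""Independent reference implementations used to check the real code.

Everything here is written as plain scalar loops or direct summation and
deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def conv_loops(x, kernels, stride=1):
    """Valid sliding-inner-product convolution, double loop."""
    x = list(x)
    out = []
    for w in kernels:
        w = list(w)
        row = []
        i = 0
        while i + len(w) <= len(x):
            row.append(sum(x[i + a] * w[a] for a in range(len(w))))
            i += stride
        out.append(row)
    return np.array(out)


def activate_loops(u, kind):
    def f(v):
        if kind == "relu":
            return max(v, 0.0)
        return 1.0 / (1.0 + math.exp(-v)) if v >= 0 else \
            math.exp(v) / (1.0 + math.exp(v))
    return np.array([[f(v) for v in row] for row in np.atleast_2d(u)])


def max_pool_loops(y, pool_len, stride):
    y = np.atleast_2d(y)
    out = []
    for row in y:
        vals = []
        c = 0
        while c + pool_len <= len(row):
            vals.append(max(row[c:c + pool_len]))
            c += stride
        out.append(vals)
    return np.array(out)


def dense_loops(flat, weights, bias):
    flat = list(np.asarray(flat).ravel())
    return np.array([
        sum(weights[j][i] * flat[i] for i in range(len(flat))) + bias[j]
        for j in range(len(bias))
    ])


def softmax_loops(u):
    e = [math.exp(v - max(u)) for v in u]
    z = sum(e)
    return np.array([v / z for v in e])


def forward_loops(x, kernels, dense_w, dense_b, *, activation,
                  pool_len=2, pool_stride=2, conv_stride=1):
    """Composed forward pass via the scalar-loop layers.

    Flattening is kernel-major (all pooled positions of kernel 0, then
    kernel 1, ...), matching the documented model layout.
    """
    maps = conv_loops(x, kernels, conv_stride)
    acts = activate_loops(maps, activation)
    pooled = max_pool_loops(acts, pool_len, pool_stride)
    flat = [v for row in pooled for v in row]
    u = dense_loops(flat, dense_w, dense_b)
    return softmax_loops(u)


def moving_average_direct(x, w):
    """Centered moving average, shrinking windows, direct summation."""
    n = len(x)
    out = []
    for i in range(n):
        lo = max(0, i - (w - 1) // 2)
        hi = min(n, i + w // 2 + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return np.array(out)


def window_means_direct(x, start, n_windows, spw):
    """Non-overlapping window means by direct summation."""
    return np.array([
        sum(x[start + i * spw: start + (i + 1) * spw]) / spw
        for i in range(n_windows)
    ])


def numerical_gradients(model, X, y, eps=1e-5):
    """Central finite differences of the mean batch loss for every
    parameter of a CNNModel.  Uses only the package's forward pass."""
    from nirscnn.cnn import forward, loss as loss_fn

    X = np.atleast_2d(X)

    def batch_loss():
        return float(np.mean([
            loss_fn(forward(model, X[s])[0], int(y[s]), model.config.loss)
            for s in range(X.shape[0])
        ]))

    grads = {}
    for name in ("kernels", "dense_w", "dense_b"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = batch_loss()
            arr[idx] = orig - eps
            lm = batch_loss()
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        grads[name] = g
    return grads
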
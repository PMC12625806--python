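"""Minimal dense/convolutional/recurrent layer kit with explicit backprop.

Parameters are float64 by default; all layers propagate the dtype of
their inputs, so a model cast to float32 computes in float32 throughout
(roughly halving memory traffic on bandwidth-bound CPUs).  Each layer
exposes ``forward(x, train)`` and
``backward(dy)``; parameters and their accumulated gradients live in the
``params`` / ``grads`` dicts keyed by name.  Convolutions are 3x3, stride 1,
"same" padding and are evaluated as a single im2col matmul so the BLAS does
the heavy lifting; the GRU runs a cached loop over time with full
backpropagation through time.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grads(self):
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Conv3x3(Layer):
    """3x3 same-padding convolution on NHWC tensors."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan_in, fan_out = 9 * in_ch, 9 * out_ch
        self.params["W"] = glorot_uniform(rng, (9 * in_ch, out_ch), fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch)
        self.in_ch = in_ch
        self.zero_grads()

    def _im2col(self, x):
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((b, h, w, 9 * c), dtype=x.dtype)
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[..., k * c : (k + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
                k += 1
        return cols

    def forward(self, x, train: bool):
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols.reshape(-1, cols.shape[-1])
        y = self._cols @ self.params["W"] + self.params["b"]
        return y.reshape(*x.shape[:3], -1)

    def backward(self, dy):
        b, h, w, _ = self._shape
        dy_flat = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += self._cols.T @ dy_flat
        self.grads["b"] += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"].T).reshape(b, h, w, 9, self.in_ch)
        dxp = np.zeros((b, h + 2, w + 2, self.in_ch), dtype=dy.dtype)
        k = 0
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[..., k, :]
                k += 1
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes (NHWC or NTF).

    Inference statistics are bias-corrected exponential running averages:
    the raw accumulators start at zero and are divided by ``1 - momentum**t``
    after ``t`` updates, so they are unbiased estimates of the batch
    statistics from the first update on.  Without the correction the
    averages stay anchored to their initialisation for the first
    ``~1/(1-momentum)`` batches, which wrecks early-stopping decisions when
    epochs are only a few batches long.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self._mean_acc = np.zeros(channels)
        self._var_acc = np.zeros(channels)
        self._updates = 0
        self.momentum = momentum
        self.eps = eps
        self.zero_grads()

    @property
    def running_mean(self):
        if self._updates == 0:
            return np.zeros_like(self._mean_acc)
        return self._mean_acc / (1.0 - self.momentum**self._updates)

    @property
    def running_var(self):
        if self._updates == 0:
            return np.ones_like(self._var_acc)
        return self._var_acc / (1.0 - self.momentum**self._updates)

    def set_running_stats(self, mean, var, updates=None):
        """Install inference statistics (e.g. from a checkpoint)."""
        self._updates = int(updates) if updates is not None else 1
        scale = 1.0 - self.momentum**self._updates
        dtype = self.params["gamma"].dtype
        self._mean_acc = np.asarray(mean, dtype=dtype) * scale
        self._var_acc = np.asarray(var, dtype=dtype) * scale

    def forward(self, x, train: bool):
        flat = x.reshape(-1, x.shape[-1])
        if train:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self._mean_acc = self.momentum * self._mean_acc + (1 - self.momentum) * mu
            self._var_acc = self.momentum * self._var_acc + (1 - self.momentum) * var
            self._updates += 1
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._mu = mu
        self._flat = flat
        self._shape = x.shape
        # fused affine: y = xhat*gamma + beta = flat*scale + shift
        scale = self.params["gamma"] / self._std
        shift = self.params["beta"] - mu * scale
        y = flat * scale + shift
        return y.reshape(x.shape)

    def backward(self, dy):
        dyf = dy.reshape(-1, dy.shape[-1])
        n = dyf.shape[0]
        xhat = (self._flat - self._mu) / self._std
        self.grads["gamma"] += (dyf * xhat).sum(axis=0)
        self.grads["beta"] += dyf.sum(axis=0)
        g = self.params["gamma"] / (self._std * n)
        dx = g * (
            n * dyf - dyf.sum(axis=0) - xhat * (dyf * xhat).sum(axis=0)
        )
        return dx.reshape(self._shape)


class MaxPool(Layer):
    """Non-overlapping (time, freq) max pooling on NHWC tensors."""

    def __init__(self, pool: tuple[int, int]):
        super().__init__()
        self.pt, self.pf = pool

    def forward(self, x, train: bool):
        b, h, w, c = x.shape
        if h % self.pt or w % self.pf:
            raise ValueError(f"shape {(h, w)} not divisible by pool {(self.pt, self.pf)}")
        ho, wo = h // self.pt, w // self.pf
        xr = x.reshape(b, ho, self.pt, wo, self.pf, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, ho, wo, c, self.pt * self.pf)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, h, w, c = self._in_shape
        ho, wo = h // self.pt, w // self.pf
        dxr = np.zeros((b, ho, wo, c, self.pt * self.pf), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(b, ho, wo, c, self.pt, self.pf).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(b, h, w, c)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.p
        self._mask = keep.astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class FlattenTime(Layer):
    """(B, T, F1, F2) -> (B, T, F1*F2): per-timestep feature flattening."""

    def forward(self, x, train: bool):
        self._shape = x.shape
        b, t = x.shape[:2]
        return x.reshape(b, t, -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Affine map applied to the last axis (works time-distributed on 3-D)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim)
        self.zero_grads()

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        xf = self._x.reshape(-1, self._x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += xf.T @ dyf
        self.grads["b"] += dyf.sum(axis=0)
        return (dyf @ self.params["W"].T).reshape(self._x.shape)


class GRULayer(Layer):
    """Batched GRU over (B, T, F), returning the full hidden sequence.

    Update gate z, reset gate r, candidate state h~:
        z_t = sigmoid(x_t W_z + h_{t-1} U_z + b_z)
        r_t = sigmoid(x_t W_r + h_{t-1} U_r + b_r)
        h~_t = tanh(x_t W_h + (r_t * h_{t-1}) U_h + b_h)
        h_t = (1 - z_t) * h_{t-1} + z_t * h~_t
    with h_0 = 0.  Backward is full BPTT.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        for gate in ("z", "r", "h"):
            self.params[f"W_{gate}"] = glorot_uniform(
                rng, (in_dim, hidden), in_dim, hidden
            )
            self.params[f"U_{gate}"] = glorot_uniform(
                rng, (hidden, hidden), hidden, hidden
            )
            self.params[f"b_{gate}"] = np.zeros(hidden)
        self.hidden = hidden
        self.zero_grads()

    def forward(self, x, train: bool):
        p = self.params
        b, t, _ = x.shape
        h = np.zeros((b, self.hidden), dtype=x.dtype)
        self._x = x
        self._cache = []
        out = np.empty((b, t, self.hidden), dtype=x.dtype)
        # precompute the input projections for all steps in one matmul each
        xz = x @ p["W_z"] + p["b_z"]
        xr = x @ p["W_r"] + p["b_r"]
        xh = x @ p["W_h"] + p["b_h"]
        for i in range(t):
            z = sigmoid(xz[:, i] + h @ p["U_z"])
            r = sigmoid(xr[:, i] + h @ p["U_r"])
            hh = np.tanh(xh[:, i] + (r * h) @ p["U_h"])
            h_new = (1 - z) * h + z * hh
            self._cache.append((h, z, r, hh))
            h = h_new
            out[:, i] = h
        return out

    def backward(self, dy):
        p, g = self.params, self.grads
        x = self._x
        b, t, _ = x.shape
        dx = np.empty_like(x)
        dh_next = np.zeros((b, self.hidden), dtype=x.dtype)
        for i in range(t - 1, -1, -1):
            h_prev, z, r, hh = self._cache[i]
            dh = dy[:, i] + dh_next
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1 - z)
            dhh_pre = dhh * (1 - hh * hh)
            drh = dhh_pre @ p["U_h"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dr_pre = dr * r * (1 - r)
            dz_pre = dz * z * (1 - z)
            xt = x[:, i]
            g["W_h"] += xt.T @ dhh_pre
            g["U_h"] += (r * h_prev).T @ dhh_pre
            g["b_h"] += dhh_pre.sum(axis=0)
            g["W_r"] += xt.T @ dr_pre
            g["U_r"] += h_prev.T @ dr_pre
            g["b_r"] += dr_pre.sum(axis=0)
            g["W_z"] += xt.T @ dz_pre
            g["U_z"] += h_prev.T @ dz_pre
            g["b_z"] += dz_pre.sum(axis=0)
            dh_prev += dr_pre @ p["U_r"].T + dz_pre @ p["U_z"].T
            dx[:, i] = (
                dhh_pre @ p["W_h"].T + dr_pre @ p["W_r"].T + dz_pre @ p["W_z"].T
            )
            dh_next = dh_prev
        return dx


class AttentionPool(Layer):
    """Context-vector attention over a hidden sequence (B, T, D) -> (B, D).

        u_t = tanh(W h_t + b);  alpha_t = softmax_t(u_t . u);  v = sum alpha_t h_t

    The trainable context vector u scores each timestep; the weights of the
    last forward pass are kept in ``.alpha`` for inspection.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (dim, dim), dim, dim)
        self.params["b"] = np.zeros(dim)
        self.params["u"] = glorot_uniform(rng, (dim,), dim, 1)
        self.zero_grads()

    def forward(self, x, train: bool):
        p = self.params
        self._h = x
        self._ut = np.tanh(x @ p["W"] + p["b"])
        scores = self._ut @ p["u"]
        self.alpha = softmax(scores, axis=1)
        return np.einsum("bt,btd->bd", self.alpha, x)

    def backward(self, dv):
        p, g = self.params, self.grads
        h, ut, alpha = self._h, self._ut, self.alpha
        dalpha = np.einsum("bd,btd->bt", dv, h)
        dh = alpha[..., None] * dv[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        g["u"] += np.einsum("bt,btd->d", ds, ut)
        dut = ds[..., None] * p["u"]
        dut_pre = dut * (1 - ut * ut)
        g["W"] += np.einsum("btd,bte->de", h, dut_pre)
        g["b"] += dut_pre.sum(axis=(0, 1))
        dh += dut_pre @ p["W"].T
        return dh


class SqueezeChannel(Layer):
    """(B, T, F, 1) -> (B, T, F): feed scalogram rows straight to a GRU."""

    def forward(self, x, train: bool):
        return x[..., 0]

    def backward(self, dy):
        return dy[..., None]


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over a batch and its logit gradient."""
    p = softmax(logits, axis=-1)
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class SGD:
    """Mini-batch stochastic gradient descent with classical momentum."""

    def __init__(self, layers, lr: float = 0.01, momentum: float = 0.9):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def step(self):
        for layer, vel in zip(self.layers, self.velocity):
            for k in layer.params:
                vel[k] = self.momentum * vel[k] - self.lr * layer.grads[k]
                layer.params[k] += vel[k]
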
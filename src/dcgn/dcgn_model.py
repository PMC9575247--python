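"""The DCGN network: FC -> reshape -> conv -> max-pool -> BiGRU -> conv ->
flatten -> 4-layer classifier, with exact reverse-mode gradients.

Layers are plain numpy objects exposing ``forward``/``backward``; the
gradient of every parameter is accumulated in ``grads`` during the
backward pass and checked against central differences in the test suite.
Convolutions are cross-correlations (no kernel flip) with "same" zero
padding, output size ``ceil(input / stride)``, the extra padding row/column
placed bottom/right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activations import activation_apply, activation_grad
from .io_config import DCGNConfig
from .preprocessing import StandardizationParams

# ---------------------------------------------------------------------------
# functional primitives


def _same_pad_amount(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


def conv2d_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    padding: str = "same",
) -> np.ndarray:
    """Strided 2-D cross-correlation over NHWC input.

    ``kernels`` has shape (kh, kw, c_in, c_out); output spatial size is
    ``ceil(input / stride)`` under "same" zero padding.
    """
    y, _ = _conv2d_with_cache(x, kernels, bias, stride, padding)
    return y


def _conv2d_with_cache(x, kernels, bias, stride, padding):
    if padding != "same":
        raise ValueError(f"unsupported padding mode {padding!r}")
    n, h, w, c = x.shape
    kh, kw, c_in, c_out = kernels.shape
    if c_in != c:
        raise ValueError(f"kernel expects {c_in} channels, input has {c}")
    oh, ph0, ph1 = _same_pad_amount(h, kh, stride)
    ow, pw0, pw1 = _same_pad_amount(w, kw, stride)
    xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    cols = np.empty((n, oh, ow, kh * kw * c), dtype=float)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
            cols[..., (i * kw + j) * c : (i * kw + j + 1) * c] = patch
    wmat = kernels.reshape(kh * kw * c, c_out)
    y = cols @ wmat
    if bias is not None:
        y = y + bias
    cache = (cols, xp.shape, (ph0, ph1, pw0, pw1), x.shape, stride, kernels.shape)
    return y, cache


def _conv2d_backward(dy, kernels, cache):
    cols, xp_shape, (ph0, ph1, pw0, pw1), x_shape, stride, kshape = cache
    kh, kw, c, c_out = kshape
    n, oh, ow, _ = dy.shape
    wmat = kernels.reshape(kh * kw * c, c_out)
    dwmat = cols.reshape(-1, kh * kw * c).T @ dy.reshape(-1, c_out)
    db = dy.sum(axis=(0, 1, 2))
    dcols = dy @ wmat.T
    dxp = np.zeros(xp_shape, dtype=float)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += (
                dcols[..., (i * kw + j) * c : (i * kw + j + 1) * c]
            )
    h, w = x_shape[1], x_shape[2]
    dx = dxp[:, ph0 : ph0 + h, pw0 : pw0 + w, :]
    return dx, dwmat.reshape(kshape), db


def maxpool_forward(
    x: np.ndarray, pool: tuple[int, int], stride: int | None = None
) -> np.ndarray:
    """Windowed per-channel maximum, no padding."""
    y, _ = _maxpool_with_cache(x, pool, stride)
    return y


def _maxpool_with_cache(x, pool, stride):
    ph, pw = pool
    if stride is None:
        stride = ph
    n, h, w, c = x.shape
    if ph > h or pw > w:
        raise ValueError(f"pool {pool} larger than input {h}x{w}")
    oh = (h - ph) // stride + 1
    ow = (w - pw) // stride + 1
    windows = np.empty((n, oh, ow, ph * pw, c), dtype=float)
    for i in range(ph):
        for j in range(pw):
            windows[:, :, :, i * pw + j, :] = x[
                :, i : i + stride * oh : stride, j : j + stride * ow : stride, :
            ]
    arg = windows.argmax(axis=3)
    y = np.take_along_axis(windows, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, (arg, x.shape, pool, stride, (oh, ow))


def _maxpool_backward(dy, cache):
    arg, x_shape, (ph, pw), stride, (oh, ow) = cache
    dx = np.zeros(x_shape, dtype=float)
    for i in range(ph):
        for j in range(pw):
            mask = arg == (i * pw + j)
            dx[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += (
                dy * mask
            )
    return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUCellParams:
    """Weights of one GRU cell acting on the concatenation [h_prev, x_t].

    Each matrix has shape ``(hidden + input, hidden)``; biases default to
    zero vectors.
    """

    W_z: np.ndarray
    W_r: np.ndarray
    W: np.ndarray
    hidden_size: int
    b_z: np.ndarray = None  # type: ignore[assignment]
    b_r: np.ndarray = None  # type: ignore[assignment]
    b: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        h = self.hidden_size
        for name in ("W_z", "W_r", "W"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[1] != h:
                raise ValueError(f"{name} must be (hidden+input, {h}), got {m.shape}")
        if self.b_z is None:
            self.b_z = np.zeros(h)
        if self.b_r is None:
            self.b_r = np.zeros(h)
        if self.b is None:
            self.b = np.zeros(h)

    @property
    def input_size(self) -> int:
        return self.W_z.shape[0] - self.hidden_size


def gru_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, params: GRUCellParams
) -> np.ndarray:
    """One GRU step.

    update gate  z = sigmoid([h_prev, x] @ W_z + b_z)
    reset gate   r = sigmoid([h_prev, x] @ W_r + b_r)
    candidate    h' = tanh([h_prev * r, x] @ W + b)
    new state    h = (1 - z) * h' + z * h_prev
    """
    was_1d = np.asarray(x_t).ndim == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if x_t.shape[1] != params.input_size or h_prev.shape[1] != params.hidden_size:
        raise ValueError(
            f"expected input {params.input_size}, hidden {params.hidden_size}; "
            f"got x {x_t.shape}, h {h_prev.shape}"
        )
    gin = np.concatenate([h_prev, x_t], axis=1)
    z = _sigmoid(gin @ params.W_z + params.b_z)
    r = _sigmoid(gin @ params.W_r + params.b_r)
    cin = np.concatenate([h_prev * r, x_t], axis=1)
    h_cand = np.tanh(cin @ params.W + params.b)
    h_t = (1.0 - z) * h_cand + z * h_prev
    return h_t[0] if was_1d else h_t


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: parameter dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, activation, rng):
        super().__init__()
        self.activation = activation
        self.params = {
            "W": _glorot(rng, n_in, n_out, (n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, training=False):
        if x.shape[1] != self.params["W"].shape[0]:
            raise ValueError(
                f"dense layer expects width {self.params['W'].shape[0]}, "
                f"input has shape {x.shape}"
            )
        self._x = x
        self._pre = x @ self.params["W"] + self.params["b"]
        return activation_apply(self.activation, self._pre)

    def backward(self, dy):
        dpre = dy * activation_grad(self.activation, self._pre)
        self.grads["W"] = self._x.T @ dpre
        self.grads["b"] = dpre.sum(axis=0)
        return dpre @ self.params["W"].T

    def out_shape(self, in_shape):
        return (self.params["W"].shape[1],)


class ReshapeToMap(Layer):
    """(N, s*s) -> (N, s, s, 1), row-major."""

    def __init__(self, n_features):
        super().__init__()
        side = int(round(np.sqrt(n_features)))
        if side * side != n_features:
            raise ValueError(f"{n_features} is not a perfect square")
        self.side = side

    def forward(self, x, training=False):
        return x.reshape(x.shape[0], self.side, self.side, 1)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)

    def out_shape(self, in_shape):
        return (self.side, self.side, 1)


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kernel_size, stride, activation, rng):
        super().__init__()
        kh, kw = kernel_size
        self.stride = stride
        self.activation = activation
        fan_in = kh * kw * c_in
        self.params = {
            "K": _glorot(rng, fan_in, c_out, (kh, kw, c_in, c_out)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training=False):
        pre, self._cache = _conv2d_with_cache(
            x, self.params["K"], self.params["b"], self.stride, "same"
        )
        self._pre = pre
        return activation_apply(self.activation, pre)

    def backward(self, dy):
        dpre = dy * activation_grad(self.activation, self._pre)
        dx, dk, db = _conv2d_backward(dpre, self.params["K"], self._cache)
        self.grads["K"] = dk
        self.grads["b"] = db
        return dx

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        kh, kw, _, c_out = self.params["K"].shape
        oh, _, _ = _same_pad_amount(h, kh, self.stride)
        ow, _, _ = _same_pad_amount(w, kw, self.stride)
        return (oh, ow, c_out)


class MaxPool2D(Layer):
    def __init__(self, pool, stride=None):
        super().__init__()
        self.pool = tuple(pool)
        self.stride = stride if stride is not None else self.pool[0]

    def forward(self, x, training=False):
        y, self._cache = _maxpool_with_cache(x, self.pool, self.stride)
        return y

    def backward(self, dy):
        return _maxpool_backward(dy, self._cache)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        oh = (h - self.pool[0]) // self.stride + 1
        ow = (w - self.pool[1]) // self.stride + 1
        return (oh, ow, c)


class MapToSequence(Layer):
    """(N, H, W, C) -> (N, T, F): rows (T=H, F=W*C) or columns (T=W, F=H*C)."""

    def __init__(self, axis="rows"):
        super().__init__()
        if axis not in ("rows", "columns"):
            raise ValueError("axis must be 'rows' or 'columns'")
        self.axis = axis

    def forward(self, x, training=False):
        self._shape = x.shape
        if self.axis == "columns":
            x = x.transpose(0, 2, 1, 3)
            self._tshape = x.shape
        n = x.shape[0]
        return x.reshape(n, x.shape[1], -1)

    def backward(self, dy):
        if self.axis == "columns":
            return dy.reshape(self._tshape).transpose(0, 2, 1, 3)
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h, w * c) if self.axis == "rows" else (w, h * c)


class SequenceToMap(Layer):
    """(N, T, F) -> (N, T, F, 1) so a conv layer can consume the sequence."""

    def forward(self, x, training=False):
        return x[..., None]

    def backward(self, dy):
        return dy[..., 0]

    def out_shape(self, in_shape):
        t, f = in_shape
        return (t, f, 1)


class _GRUDirection:
    """One direction of a BiGRU with full backpropagation through time."""

    def __init__(self, n_in, hidden, rng, reverse):
        self.hidden = hidden
        self.reverse = reverse
        tot = hidden + n_in
        self.params = {
            "Wz": _glorot(rng, tot, hidden, (tot, hidden)),
            "Wr": _glorot(rng, tot, hidden, (tot, hidden)),
            "Wh": _glorot(rng, tot, hidden, (tot, hidden)),
            "bz": np.zeros(hidden),
            "br": np.zeros(hidden),
            "bh": np.zeros(hidden),
        }
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x):
        n, t, _ = x.shape
        order = range(t - 1, -1, -1) if self.reverse else range(t)
        h = np.zeros((n, self.hidden))
        self._cache = []
        out = np.empty((n, t, self.hidden))
        p = self.params
        for step in order:
            x_t = x[:, step, :]
            gin = np.concatenate([h, x_t], axis=1)
            z = _sigmoid(gin @ p["Wz"] + p["bz"])
            r = _sigmoid(gin @ p["Wr"] + p["br"])
            cin = np.concatenate([h * r, x_t], axis=1)
            hc = np.tanh(cin @ p["Wh"] + p["bh"])
            h_new = (1.0 - z) * hc + z * h
            self._cache.append((step, gin, cin, z, r, hc, h))
            h = h_new
            out[:, step, :] = h
        return out

    def backward(self, dout, dx):
        p = self.params
        self.grads = {k: np.zeros_like(v) for k, v in p.items()}
        hsz = self.hidden
        dh_next = np.zeros_like(dout[:, 0, :])
        for step, gin, cin, z, r, hc, h_prev in reversed(self._cache):
            dh = dout[:, step, :] + dh_next
            dz = dh * (h_prev - hc)
            dhc = dh * (1.0 - z)
            dh_prev = dh * z
            # candidate branch
            dhc_pre = dhc * (1.0 - hc**2)
            self.grads["Wh"] += cin.T @ dhc_pre
            self.grads["bh"] += dhc_pre.sum(axis=0)
            dcin = dhc_pre @ p["Wh"].T
            dhr = dcin[:, :hsz]
            dx_t = dcin[:, hsz:].copy()
            dr = dhr * h_prev
            dh_prev = dh_prev + dhr * r
            # gates
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            self.grads["Wz"] += gin.T @ dz_pre
            self.grads["bz"] += dz_pre.sum(axis=0)
            self.grads["Wr"] += gin.T @ dr_pre
            self.grads["br"] += dr_pre.sum(axis=0)
            dgin = dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            dh_prev = dh_prev + dgin[:, :hsz]
            dx_t += dgin[:, hsz:]
            dx[:, step, :] += dx_t
            dh_next = dh_prev
        return dx


class BiGRU(Layer):
    """Bidirectional GRU over (N, T, F); output concatenates both
    directions' per-step hidden states into (N, T, 2*hidden)."""

    def __init__(self, n_in, hidden, rng):
        super().__init__()
        self.hidden = hidden
        self.fwd = _GRUDirection(n_in, hidden, rng, reverse=False)
        self.bwd = _GRUDirection(n_in, hidden, rng, reverse=True)
        self.params = {}
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in d.params.items():
                self.params[f"{tag}_{k}"] = v

    def forward(self, x, training=False):
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        self._xshape = x.shape
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=2)

    def backward(self, dy):
        h = self.hidden
        dx = np.zeros(self._xshape)
        self.fwd.backward(dy[:, :, :h], dx)
        self.bwd.backward(dy[:, :, h:], dx)
        self.grads = {}
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in d.grads.items():
                self.grads[f"{tag}_{k}"] = v
        return dx

    def out_shape(self, in_shape):
        t, _ = in_shape
        return (t, 2 * self.hidden)


def bigru_forward(
    sequence: np.ndarray, fwd: GRUCellParams, bwd: GRUCellParams
) -> np.ndarray:
    """Reference bidirectional pass over a single (T, F) sequence using
    :func:`gru_cell_step`; returns (T, 2*hidden)."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be (T, F) with T >= 1")
    t = seq.shape[0]
    out_f = np.zeros((t, fwd.hidden_size))
    h = np.zeros(fwd.hidden_size)
    for step in range(t):
        h = gru_cell_step(seq[step], h, fwd)
        out_f[step] = h
    out_b = np.zeros((t, bwd.hidden_size))
    h = np.zeros(bwd.hidden_size)
    for step in range(t - 1, -1, -1):
        h = gru_cell_step(seq[step], h, bwd)
        out_b[step] = h
    return np.concatenate([out_f, out_b], axis=1)


class Dropout(Layer):
    """Inverted dropout; active only when the training flag is set."""

    def __init__(self, rate, rng):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


# ---------------------------------------------------------------------------
# the assembled network


class LayerStack:
    """Ordered DCGN layers with a verified shape chain."""

    def __init__(self, layers: list[Layer], config: DCGNConfig, n_genes: int):
        self.layers = layers
        self.config = config
        self.n_genes = n_genes
        self.shape_chain = self._verify_shapes()

    def _verify_shapes(self) -> list[tuple]:
        shape: tuple = (self.n_genes,)
        chain = [shape]
        for layer in self.layers:
            try:
                shape = layer.out_shape(shape)
            except Exception as exc:  # noqa: BLE001 - reported with context
                raise ValueError(
                    f"shape chain broken at {type(layer).__name__} with input "
                    f"{shape}: {exc}"
                ) from exc
            chain.append(shape)
        if shape != (self.config.n_classes,):
            raise ValueError(
                f"network ends at {shape}, expected ({self.config.n_classes},)"
            )
        return chain

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_genes:
            raise ValueError(
                f"input must be (N, {self.n_genes}), got {x.shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i}__{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"layer{i}__{k}"] = v
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = values[f"layer{i}__{k}"]
                # BiGRU directions share arrays with layer.params in-place

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())


def build_dcgn(config: DCGNConfig, n_genes: int) -> LayerStack:
    """Assemble the network for ``n_genes`` input features.

    Default chain: n_genes -> FC(1024, gelu) -> (32,32,1) -> conv(128 k,
    3x3, stride 2, same) -> (16,16,128) -> max-pool(2x2) -> (8,8,128) ->
    BiGRU over spatial rows (T=8, F=1024, 64 units per direction) ->
    (8,128) -> conv(64 k, 3x3, stride 2, same) -> (4,64,64) -> flatten ->
    128 -> 64 -> 32 -> n_classes, dropout 0.6/0.6/0.7 after the hidden
    classifier layers, logits out.  Weight init is uniform Glorot under
    ``config.seed``; biases start at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    act = config.activation
    layers: list[Layer] = []

    layers.append(Dense(n_genes, config.fc_nodes, act, rng))
    layers.append(ReshapeToMap(config.fc_nodes))
    layers.append(
        Conv2D(1, config.conv1_kernels, config.kernel_size, config.conv_strides, act, rng)
    )
    layers.append(MaxPool2D(config.pool_size))
    seq = MapToSequence(config.bigru_sequence_axis)
    layers.append(seq)

    # track shapes to size the recurrent and dense layers
    shape: tuple = (n_genes,)
    for layer in layers:
        shape = layer.out_shape(shape)
    t_steps, feat = shape
    layers.append(BiGRU(feat, config.gru_units, rng))
    layers.append(SequenceToMap())
    layers.append(
        Conv2D(1, config.conv2_kernels, config.kernel_size, config.conv_strides, act, rng)
    )
    layers.append(Flatten())
    shape = (t_steps, feat)
    for layer in layers[5:]:
        shape = layer.out_shape(shape)
    width = shape[0]

    r1, r2 = config.dropout_rates
    rates = (r1, r1, r2)
    for i, nodes in enumerate(config.classifier_nodes):
        layers.append(Dense(width, nodes, act, rng))
        rate = rates[i] if i < len(rates) else rates[-1]
        layers.append(Dropout(rate, np.random.default_rng([config.seed, 1000 + i])))
        width = nodes
    layers.append(Dense(width, config.n_classes, "linear", rng))

    return LayerStack(layers, config, n_genes)


def dcgn_forward(
    model: LayerStack, x: np.ndarray, training: bool = False
) -> np.ndarray:
    """Raw class scores (logits) for a batch; no terminal softmax."""
    return model.forward(np.asarray(x, dtype=float), training=training)


@dataclass
class TrainedDCGN:
    """A trained network plus everything needed to score new samples."""

    model: LayerStack
    config: DCGNConfig
    standardizer: StandardizationParams | None
    label_names: list[str]

    def predict_logits(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.standardizer is not None:
            std = self.standardizer.std.copy()
            constant = std < 1e-12 * np.maximum(1.0, np.abs(self.standardizer.mean))
            std[constant] = 1.0
            x = (x - self.standardizer.mean) / std
            x[:, constant] = 0.0
        return self.model.forward(x, training=False)

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Argmax class codes; ties resolve to the lowest class index."""
        return self.predict_logits(values).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.config.save(path / "config.json")
        np.savez(path / "weights.npz", **self.model.parameters())
        meta = {"n_genes": self.model.n_genes, "label_names": self.label_names}
        (path / "meta.json").write_text(json.dumps(meta))
        if self.standardizer is not None:
            self.standardizer.save(path / "standardizer.json")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedDCGN":
        path = Path(path)
        config = DCGNConfig.load(path / "config.json")
        meta = json.loads((path / "meta.json").read_text())
        model = build_dcgn(config, meta["n_genes"])
        with np.load(path / "weights.npz") as npz:
            model.set_parameters(dict(npz))
        standardizer = None
        if (path / "standardizer.json").exists():
            standardizer = StandardizationParams.load(path / "standardizer.json")
        return cls(model, config, standardizer, meta["label_names"])
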
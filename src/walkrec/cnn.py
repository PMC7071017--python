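"""Small 1-D convolutional networks for raw-signal walking classification.

Two fixed architectures operate on a single 250-sample channel (either the
vertical projected acceleration or the acceleration norm):

* architecture **a**: conv(3,10) → conv(3,10) → maxpool(2) → dropout →
  flatten → dense(128) → dropout → dense(2) — 158,176 parameters;
* architecture **b**: conv(3,5) → maxpool(2) → conv(3,10) → maxpool(2) →
  flatten → dense(1024) → dropout → dense(2) — 627,894 parameters.

Convolutions use valid padding and stride 1 with ReLU; pooling halves the
length (floor).  Training uses softmax cross-entropy with the Adam
optimizer (default rate 1e-3), 64 epochs, batch size 128 and dropout rate
0.2.  The forward/backward passes are implemented directly in numpy; the
networks are small enough that this trains in seconds at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LayerSpec", "CnnSpec", "build_cnn_spec", "count_parameters", "Cnn1d", "train_cnn"]


@dataclass
class LayerSpec:
    name: str
    kind: str  # conv1d | maxpool1d | dropout | flatten | dense
    kernel_size: int | None = None
    n_kernels: int | None = None
    stride: int | None = None
    units: int | None = None
    output_shape: tuple = ()
    param_count: int = 0


@dataclass
class CnnSpec:
    arch: str
    input_len: int
    layers: list[LayerSpec]

    @property
    def total_params(self) -> int:
        return sum(l.param_count for l in self.layers)


_ARCHS = {
    "a": [
        ("conv1_a", "conv1d", dict(kernel_size=3, n_kernels=10, stride=1)),
        ("conv2_a", "conv1d", dict(kernel_size=3, n_kernels=10, stride=1)),
        ("max_pool_a", "maxpool1d", dict(kernel_size=2)),
        ("dropout1_a", "dropout", {}),
        ("flattening_a", "flatten", {}),
        ("fully_con1_a", "dense", dict(units=128)),
        ("dropout2_a", "dropout", {}),
        ("fully_con2_a", "dense", dict(units=2)),
    ],
    "b": [
        ("conv1_b", "conv1d", dict(kernel_size=3, n_kernels=5, stride=1)),
        ("max_pool1_b", "maxpool1d", dict(kernel_size=2)),
        ("conv2_b", "conv1d", dict(kernel_size=3, n_kernels=10, stride=1)),
        ("max_pool2_b", "maxpool1d", dict(kernel_size=2)),
        ("flattening_b", "flatten", {}),
        ("fully_con1_b", "dense", dict(units=1024)),
        ("dropout_b", "dropout", {}),
        ("fully_con2_b", "dense", dict(units=2)),
    ],
}


def build_cnn_spec(arch: str, input_len: int = 250) -> CnnSpec:
    """Layer-by-layer specification with chained shapes and parameter counts.

    Shape rules: valid conv, out_len = in_len − kernel + 1; pooling,
    out_len = ⌊in_len / 2⌋; dense layers connect all flattened units.
    Parameter rules: conv (kernel·in_channels + 1)·out_channels; dense
    (in + 1)·out; pool/dropout/flatten contribute none.
    """
    if arch not in _ARCHS:
        raise ValueError(f"unknown architecture {arch!r}; choose 'a' or 'b'")
    layers: list[LayerSpec] = []
    length, channels = input_len, 1
    flat: int | None = None
    for name, kind, kw in _ARCHS[arch]:
        if kind == "conv1d":
            ksz, nk = kw["kernel_size"], kw["n_kernels"]
            length = length - ksz + 1
            params = (ksz * channels + 1) * nk
            channels = nk
            layers.append(LayerSpec(name, kind, kernel_size=ksz, n_kernels=nk,
                                    stride=kw["stride"], output_shape=(length, channels),
                                    param_count=params))
        elif kind == "maxpool1d":
            length = length // 2
            layers.append(LayerSpec(name, kind, kernel_size=kw["kernel_size"],
                                    output_shape=(length, channels)))
        elif kind == "dropout":
            shape = (flat,) if flat is not None else (length, channels)
            layers.append(LayerSpec(name, kind, output_shape=shape))
        elif kind == "flatten":
            flat = length * channels
            layers.append(LayerSpec(name, kind, output_shape=(flat,)))
        elif kind == "dense":
            if flat is None:
                raise ValueError("dense layer before flatten")
            units = kw["units"]
            layers.append(LayerSpec(name, kind, units=units, output_shape=(units,),
                                    param_count=(flat + 1) * units))
            flat = units
    return CnnSpec(arch=arch, input_len=input_len, layers=layers)


def count_parameters(spec: CnnSpec) -> int:
    """Total trainable parameters, re-derived from the layer chain."""
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv1d" or layer.kind == "dense":
            if layer.param_count <= 0:
                raise ValueError(f"inconsistent spec: {layer.name} has no parameters")
        total += layer.param_count
    return total


# ------------------------------------------------------------ numpy backend

def _conv1d_forward(x, w, b):
    # x: (B, L, Cin); w: (K, Cin, Cout); valid padding, stride 1
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, L-K+1, Cin, K)
    return np.einsum("blck,kco->blo", win, w) + b


def _conv1d_backward(x, w, grad_out):
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    gw = np.einsum("blck,blo->kco", win, grad_out)
    gb = grad_out.sum(axis=(0, 1))
    gx = np.zeros_like(x)
    for i in range(k):
        gx[:, i:i + grad_out.shape[1], :] += np.einsum("blo,kco->blc", grad_out, w[i:i + 1])
    return gx, gw, gb


class Cnn1d:
    """A trained (or trainable) instance of one of the printed architectures."""

    def __init__(self, spec: CnnSpec, seed: int = 0, dropout_rate: float = 0.2):
        self.spec = spec
        self.dropout_rate = dropout_rate
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.history: list[float] = []
        channels = 1
        flat = None
        for layer in spec.layers:
            if layer.kind == "conv1d":
                fan_in = layer.kernel_size * channels
                scale = np.sqrt(2.0 / fan_in)
                self.params[f"{layer.name}.w"] = self.rng.normal(
                    0, scale, (layer.kernel_size, channels, layer.n_kernels))
                self.params[f"{layer.name}.b"] = np.zeros(layer.n_kernels)
                channels = layer.n_kernels
            elif layer.kind == "flatten":
                flat = layer.output_shape[0]
            elif layer.kind == "dense":
                scale = np.sqrt(2.0 / flat)
                self.params[f"{layer.name}.w"] = self.rng.normal(0, scale, (flat, layer.units))
                self.params[f"{layer.name}.b"] = np.zeros(layer.units)
                flat = layer.units

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _forward(self, x, train: bool):
        cache = []
        h = x[:, :, None]  # (B, 250, 1)
        last_dense = self.spec.layers[-1].name
        for layer in self.spec.layers:
            if layer.kind == "conv1d":
                w, b = self.params[f"{layer.name}.w"], self.params[f"{layer.name}.b"]
                z = _conv1d_forward(h, w, b)
                a = np.maximum(z, 0.0)
                cache.append((layer, h, z))
                h = a
            elif layer.kind == "maxpool1d":
                b_, l_, c_ = h.shape
                l2 = l_ // 2
                blocks = h[:, :l2 * 2, :].reshape(b_, l2, 2, c_)
                arg = blocks.argmax(axis=2)
                cache.append((layer, h.shape, arg))
                h = blocks.max(axis=2)
            elif layer.kind == "dropout":
                if train and self.dropout_rate > 0:
                    mask = (self.rng.random(h.shape) >= self.dropout_rate) / (1 - self.dropout_rate)
                else:
                    mask = None
                cache.append((layer, mask, None))
                if mask is not None:
                    h = h * mask
            elif layer.kind == "flatten":
                cache.append((layer, h.shape, None))
                h = h.reshape(h.shape[0], -1)
            elif layer.kind == "dense":
                w, b = self.params[f"{layer.name}.w"], self.params[f"{layer.name}.b"]
                z = h @ w + b
                if layer.name == last_dense:
                    cache.append((layer, h, None))  # logits, no ReLU
                    h = z
                else:
                    cache.append((layer, h, z))
                    h = np.maximum(z, 0.0)
        return h, cache

    def _backward(self, grad, cache):
        grads = {}
        for layer, a, z in reversed(cache):
            if layer.kind == "dense":
                if z is not None:  # hidden dense: ReLU
                    grad = grad * (z > 0)
                w = self.params[f"{layer.name}.w"]
                grads[f"{layer.name}.w"] = a.T @ grad
                grads[f"{layer.name}.b"] = grad.sum(axis=0)
                grad = grad @ w.T
            elif layer.kind == "flatten":
                grad = grad.reshape(a)
            elif layer.kind == "dropout":
                if a is not None:
                    grad = grad * a
            elif layer.kind == "maxpool1d":
                shape, arg = a, z
                b_, l_, c_ = shape
                l2 = l_ // 2
                g = np.zeros((b_, l2, 2, c_))
                bi = np.arange(b_)[:, None, None]
                li = np.arange(l2)[None, :, None]
                ci = np.arange(c_)[None, None, :]
                g[bi, li, arg, ci] = grad
                full = np.zeros((b_, l_, c_))
                full[:, :l2 * 2, :] = g.reshape(b_, l2 * 2, c_)
                grad = full
            elif layer.kind == "conv1d":
                grad = grad * (z > 0)
                w = self.params[f"{layer.name}.w"]
                gx, gw, gb = _conv1d_backward(a, w, grad)
                grads[f"{layer.name}.w"] = gw
                grads[f"{layer.name}.b"] = gb
                grad = gx
        return grads

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self._forward(np.asarray(x, dtype=float), train=False)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def fit(self, x, y, epochs: int = 64, batch_size: int = 128, lr: float = 1e-3):
        """Adam + softmax cross-entropy; records mean loss per epoch."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(x)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                idx = order[s:s + batch_size]
                xb, yb = x[idx], y[idx]
                logits, cache = self._forward(xb, train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                p = e / e.sum(axis=1, keepdims=True)
                losses.append(float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12))))
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad /= len(yb)
                grads = self._backward(grad, cache)
                step += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mh = m[k] / (1 - b1 ** step)
                    vh = v[k] / (1 - b2 ** step)
                    self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
            self.history.append(float(np.mean(losses)))
        return self


def train_cnn(spec: CnnSpec, windows, labels, epochs: int = 64, batch_size: int = 128,
              dropout: float = 0.2, lr: float = 1e-3, seed: int = 0) -> Cnn1d:
    """Train one of the printed architectures on (n, 250) 1-D inputs.

    Inputs are single channels — the vertical projected acceleration for
    the ``.1`` variants or the acceleration norm for ``.2``.  Emits a
    warning when the minority class is under 10%.
    """
    import warnings

    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() / max(counts.sum(), 1) < 0.10:
        warnings.warn("minority class below 10%: consider rebalancing", stacklevel=2)
    model = Cnn1d(spec, seed=seed, dropout_rate=dropout)
    model.fit(np.asarray(windows, dtype=float), y, epochs=epochs,
              batch_size=batch_size, lr=lr)
    return model
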
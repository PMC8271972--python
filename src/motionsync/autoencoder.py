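"""Convolutional autoencoder embedding for motion curves.

A small 1-D convolutional autoencoder, implemented directly on NumPy with
manual backpropagation and Adam.  The encoder takes a length-1500 trace,
lifts it to 4 channels with a stride-1 convolution, then halves the
temporal length five times with stride-2 convolutions (kernel 3, unit
padding), giving lengths 1500 -> 750 -> 375 -> 188 -> 94 -> 47; the
flattened 4 x 47 = 188 activations are the embedding.  Encoder layers use
ReLU; the decoder mirrors the encoder with transposed convolutions and no
activation.  Training minimizes mean squared reconstruction error and the
training set is doubled by adding every trace reversed in time, a cheap
augmentation that preserves the kinematic vocabulary of the curves.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

INPUT_LENGTH = 1500
EMBEDDING_DIM = 188
_CHANNELS = 4
_KERNEL = 3
_PAD = 1
#: temporal lengths along the encoder
_ENC_LENGTHS = (1500, 1500, 750, 375, 188, 94, 47)


def _im2col(x: np.ndarray, stride: int):
    """x (N, C, L) zero-padded -> patches (N, C, K, Lout)."""
    n, c, L = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (_PAD, _PAD)))
    lout = (L + 2 * _PAD - _KERNEL) // stride + 1
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, _KERNEL, lout),
        strides=(s0, s1, s2, s2 * stride),
        writeable=False,
    )
    return cols, lout


def _col2im(gcols: np.ndarray, L: int, stride: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back to (N, C, L)."""
    n, c, _, lout = gcols.shape
    gp = np.zeros((n, c, L + 2 * _PAD))
    idx = np.arange(lout) * stride
    for k in range(_KERNEL):
        np.add.at(gp, (slice(None), slice(None), idx + k), gcols[:, :, k, :])
    return gp[:, :, _PAD : _PAD + L]


class _Conv1d:
    """Correlation layer, kernel 3, unit padding, given stride."""

    def __init__(self, cin, cout, stride, rng):
        scale = np.sqrt(2.0 / (cin * _KERNEL))
        self.W = rng.normal(0.0, scale, size=(cout, cin, _KERNEL))
        self.b = np.zeros(cout)
        self.stride = stride
        self._cache = None

    def forward(self, x):
        cols, _ = _im2col(x, self.stride)
        self._cache = (x.shape, cols)
        return np.einsum("ock,nckl->nol", self.W, cols, optimize=True) + self.b[None, :, None]

    def backward(self, gy):
        (xshape, cols) = self._cache
        self.gb = gy.sum(axis=(0, 2))
        self.gW = np.einsum("nol,nckl->ock", gy, cols, optimize=True)
        gcols = np.einsum("ock,nol->nckl", self.W, gy, optimize=True)
        return _col2im(gcols, xshape[2], self.stride)

    def params(self):
        return [(self.W, "gW"), (self.b, "gb")]


class _ConvT1d:
    """Transposed convolution (stride-2 upsampling or stride-1), kernel 3,
    unit padding, with per-layer output length fixed at construction."""

    def __init__(self, cin, cout, stride, lout, rng):
        scale = np.sqrt(2.0 / (cin * _KERNEL))
        self.W = rng.normal(0.0, scale, size=(cin, cout, _KERNEL))
        self.b = np.zeros(cout)
        self.stride = stride
        self.lout = lout
        self._cache = None

    def _full_len(self, lin):
        return (lin - 1) * self.stride + _KERNEL

    def forward(self, x):
        n, cin, lin = x.shape
        self._cache = x
        full = np.zeros((n, self.W.shape[1], self._full_len(lin)))
        contrib = np.einsum("iok,nil->nokl", self.W, x, optimize=True)
        idx = np.arange(lin) * self.stride
        for k in range(_KERNEL):
            np.add.at(full, (slice(None), slice(None), idx + k), contrib[:, :, k, :])
        start = _PAD
        y = full[:, :, start : start + self.lout]
        return y + self.b[None, :, None]

    def backward(self, gy):
        x = self._cache
        n, cin, lin = x.shape
        self.gb = gy.sum(axis=(0, 2))
        gfull = np.zeros((n, self.W.shape[1], self._full_len(lin)))
        gfull[:, :, _PAD : _PAD + self.lout] = gy
        idx = np.arange(lin) * self.stride
        G = np.stack([gfull[:, :, idx + k] for k in range(_KERNEL)], axis=2)
        self.gW = np.einsum("nil,nokl->iok", x, G, optimize=True)
        return np.einsum("iok,nokl->nil", self.W, G, optimize=True)

    def params(self):
        return [(self.W, "gW"), (self.b, "gb")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def params(self):
        return []


class ConvAutoencoder:
    """Encoder/decoder pair with a fixed 188-dimensional bottleneck.

    ``scale`` standardizes input amplitude (degrees) before the network;
    it is fit from the training data so embeddings are comparable across
    cohorts of different amplitude.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder: list = []
        cin = 1
        for li in range(6):
            stride = 1 if li == 0 else 2
            self.encoder.append(_Conv1d(cin, _CHANNELS, stride, rng))
            self.encoder.append(_ReLU())
            cin = _CHANNELS
        dec_lengths = _ENC_LENGTHS[:-1][::-1]  # 94, 188, 375, 750, 1500, 1500
        self.decoder: list = []
        for li in range(5):
            self.decoder.append(_ConvT1d(_CHANNELS, _CHANNELS, 2, dec_lengths[li], rng))
        self.decoder.append(_ConvT1d(_CHANNELS, 1, 1, INPUT_LENGTH, rng))
        self.scale = 1.0
        self.loss_history: list[float] = []
        self.n_training = 0

    # ------------------------------------------------------------------
    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != INPUT_LENGTH:
            raise InvalidInputError(
                f"architecture is length-specific: expected {INPUT_LENGTH} "
                f"samples, got {x.shape[-1]}"
            )
        return x[:, None, :]  # (N, 1, L)

    def _forward(self, xb):
        h = xb
        for layer in self.encoder:
            h = layer.forward(h)
        emb = h
        for layer in self.decoder:
            h = layer.forward(h)
        return emb, h

    def _backward(self, grad):
        for layer in reversed(self.decoder):
            grad = layer.backward(grad)
        for layer in reversed(self.encoder):
            grad = layer.backward(grad)

    def _layers(self):
        return self.encoder + self.decoder

    # ------------------------------------------------------------------
    def encode(self, values) -> np.ndarray:
        """Map one length-1500 trace to its 188-dimensional embedding."""
        xb = self._check(np.asarray(getattr(values, "values", values))) / self.scale
        h = xb
        for layer in self.encoder:
            h = layer.forward(h)
        out = h.reshape(h.shape[0], -1)
        if out.shape[1] != EMBEDDING_DIM:
            raise InvalidInputError("unexpected embedding width")  # pragma: no cover
        return out[0] if out.shape[0] == 1 else out

    def reconstruct(self, values) -> np.ndarray:
        xb = self._check(np.asarray(getattr(values, "values", values))) / self.scale
        _, y = self._forward(xb)
        return y[:, 0, :] * self.scale

    def fit(self, X: np.ndarray, epochs: int, batch_size: int, lr: float, seed: int):
        """Adam on mean squared reconstruction error; records epoch losses."""
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        xb_all = X[:, None, :]
        state = {}
        t = 0
        for ep in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = xb_all[idx]
                _, y = self._forward(xb)
                diff = y - xb
                loss = float(np.mean(diff**2))
                ep_loss += loss * len(idx)
                grad = 2.0 * diff / diff.size
                self._backward(grad)
                t += 1
                for li, layer in enumerate(self._layers()):
                    for pi, (p, gname) in enumerate(layer.params()):
                        g = getattr(layer, gname)
                        key = (li, pi)
                        m, v = state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                        m = 0.9 * m + 0.1 * g
                        v = 0.999 * v + 0.001 * g * g
                        state[key] = (m, v)
                        mhat = m / (1 - 0.9**t)
                        vhat = v / (1 - 0.999**t)
                        p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            self.loss_history.append(ep_loss / n)
        return self


def train_autoencoder(
    series,
    seed: int = 0,
    epochs: int = 200,
    batch_size: int = 32,
    lr: float = 1e-3,
) -> ConvAutoencoder:
    """Train on all given traces plus their time-reversed copies.

    Every input must have length 1500.  The returned model is a pure
    function of the inputs, seed, and schedule.
    """
    X = np.stack(
        [np.asarray(getattr(s, "values", s), dtype=float) for s in series]
    )
    if X.shape[1] != INPUT_LENGTH:
        raise InvalidInputError(
            f"architecture is length-specific: expected {INPUT_LENGTH} samples"
        )
    X = np.vstack([X, X[:, ::-1]])  # reversed-series augmentation
    model = ConvAutoencoder(seed=seed)
    model.n_training = X.shape[0]
    scale = float(X.std())
    model.scale = scale if scale > 0 else 1.0
    model.fit(X / model.scale, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed + 1)
    return model
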
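"""A small convolutional network on spectrogram images, in pure numpy.

Stands in for the full-scale image-classification topologies (AlexNet,
VGG, ResNet, Inception, MobileNet): four conv(3x3)-ReLU-maxpool blocks,
global average pooling and a dense softmax head, trained with Adam on
mini-batches.  Deliberately dependency-free so training is reproducible
bit-for-bit from a seed on any machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BreathCNN"]


def _im2col_indices(C: int, H: int, W: int, k: int = 3):
    i0 = np.tile(np.repeat(np.arange(k), k), C)
    j0 = np.tile(np.arange(k), k * C)
    i1 = np.repeat(np.arange(H), W)
    j1 = np.tile(np.arange(W), H)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    c = np.repeat(np.arange(C), k * k)[:, None]
    return c, i, j


class _Conv3x3:
    """3x3 convolution, stride 1, pad 1 (same spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self._idx = None
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self._idx is None or self._idx_shape != (c, h, w):
            self._idx = _im2col_indices(c, h, w)
            self._idx_shape = (c, h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ci, ii, jj = self._idx
        cols = xp[:, ci, ii, jj]  # (n, c*9, h*w)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("of,nfp->nop", wmat, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray):
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        dmat = dout.reshape(n, dout.shape[1], -1)
        self.dw = np.einsum("nop,nfp->of", dmat, cols).reshape(self.w.shape)
        self.db = dmat.sum(axis=(0, 2))
        wmat = self.w.reshape(self.w.shape[0], -1)
        dcols = np.einsum("of,nop->nfp", wmat, dmat)
        dxp = np.zeros((n, c, h + 2, w + 2))
        ci, ii, jj = self._idx
        np.add.at(dxp, (slice(None), ci, ii, jj), dcols)
        return dxp[:, :, 1:-1, 1:-1]

    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        self._mask = r == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)

    def params(self):
        return []

    def grads(self):
        return []


class BreathCNN:
    """Mini CNN classifier for fixed-size grayscale spectrogram images.

    Parameters
    ----------
    input_size
        Side length of the square input; must be divisible by
        ``2 ** len(channels)``.
    channels
        Output channels of the successive conv blocks.
    """

    def __init__(
        self,
        n_classes: int,
        input_size: int = 128,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        lr: float = 1e-3,
        batch_size: int = 32,
        max_steps: int = 2000,
        seed: int = 0,
    ):
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input_size {input_size} must be divisible by {2 ** len(channels)}"
            )
        self.n_classes = n_classes
        self.input_size = input_size
        self.channels = tuple(channels)
        self.lr = lr
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = 1
        for c_out in channels:
            self.layers += [_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()]
            c_in = c_out
        scale = np.sqrt(2.0 / c_in)
        self.fc_w = rng.standard_normal((c_in, n_classes)) * scale
        self.fc_b = np.zeros(n_classes)
        self.loss_history: list[float] = []
        self._adam_state = None

    # -- forward/backward ------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        self._gap_in_shape = h.shape
        g = h.mean(axis=(2, 3))  # global average pool
        self._gap_out = g
        return g @ self.fc_w + self.fc_b

    def _backward(self, dlogits: np.ndarray):
        self.d_fc_w = self._gap_out.T @ dlogits
        self.d_fc_b = dlogits.sum(axis=0)
        dg = dlogits @ self.fc_w.T
        n, c, h, w = self._gap_in_shape
        dh = np.broadcast_to(dg[:, :, None, None], (n, c, h, w)) / (h * w)
        d = dh
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def _all_params(self):
        ps = []
        for layer in self.layers:
            ps += layer.params()
        return ps + [self.fc_w, self.fc_b]

    def _all_grads(self):
        gs = []
        for layer in self.layers:
            gs += layer.grads()
        return gs + [self.d_fc_w, self.d_fc_b]

    # -- training --------------------------------------------------------
    def fit(self, images: np.ndarray, y: np.ndarray) -> "BreathCNN":
        """Train with softmax cross-entropy and Adam.

        ``images`` has shape (n, input_size, input_size); ``y`` holds
        integer class indices in ``[0, n_classes)``.
        """
        images = np.asarray(images, dtype=np.float64)
        y = np.asarray(y)
        if images.ndim != 3 or images.shape[1:] != (self.input_size, self.input_size):
            raise ValueError(
                f"expected images of shape (n, {self.input_size}, {self.input_size}), "
                f"got {images.shape}"
            )
        rng = np.random.default_rng(self.seed + 1)
        m = [np.zeros_like(p) for p in self._all_params()]
        v = [np.zeros_like(p) for p in self._all_params()]
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = len(images)
        for step in range(1, self.max_steps + 1):
            idx = rng.choice(n, size=min(self.batch_size, n), replace=False)
            xb = images[idx][:, None, :, :]
            yb = y[idx]
            logits = self._forward(xb)
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            loss = float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12)))
            self.loss_history.append(loss)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            self._backward(dlogits)
            for k, (param, grad) in enumerate(zip(self._all_params(), self._all_grads())):
                m[k] = b1 * m[k] + (1 - b1) * grad
                v[k] = b2 * v[k] + (1 - b2) * grad**2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                param -= self.lr * mh / (np.sqrt(vh) + eps)
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 3 or images.shape[1:] != (self.input_size, self.input_size):
            raise ValueError(
                f"expected images of shape (n, {self.input_size}, {self.input_size}), "
                f"got {images.shape}"
            )
        out = []
        for i in range(0, len(images), 64):
            logits = self._forward(images[i : i + 64][:, None, :, :])
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            out.append(p / p.sum(axis=1, keepdims=True))
        return np.vstack(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=1)
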
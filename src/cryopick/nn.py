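"""A small, self-contained convolutional network engine (numpy, CPU).

Implements exactly what the particle classifier needs: 'same'-padded 3x3
convolutions, ReLU, 2x2 max pooling, dense layers, a two-way softmax with
cross-entropy loss, and Adam.  Activations are kept in channels-last
``(batch, height, width, channels)`` layout so that im2col reduces to
nine contiguous slab copies and convolution to one BLAS GEMM per layer.
Layers reuse persistent scratch buffers across steps (allocation and the
page faults it brings cost more than the arithmetic at these sizes),
which keeps a 30-epoch training run on a few thousand 64x64 crops in the
minutes range on a single CPU core.

All randomness (weight init, batch shuffling) flows from an explicit
seed, so identically seeded runs are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "softmax", "cross_entropy"]

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


class _Buffers:
    """Shape-keyed scratch-buffer pool so hot arrays are allocated once."""

    def __init__(self):
        self._pool: dict[tuple, np.ndarray] = {}

    def get(self, key: str, shape: tuple, dtype=np.float32) -> np.ndarray:
        k = (key, shape, np.dtype(dtype))
        buf = self._pool.get(k)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._pool[k] = buf
        return buf


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init
        self.w = (rng.standard_normal((9 * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._buf = _Buffers()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        xp = self._buf.get("xp", (B, H + 2, W + 2, C))
        xp[:, 0, :, :] = 0.0
        xp[:, -1, :, :] = 0.0
        xp[:, :, 0, :] = 0.0
        xp[:, :, -1, :] = 0.0
        xp[:, 1 : 1 + H, 1 : 1 + W, :] = x
        cols = self._buf.get("cols", (B, H, W, 9 * C))
        for k, (di, dj) in enumerate(_OFFSETS):
            cols[:, :, :, k * C : (k + 1) * C] = xp[:, di : di + H, dj : dj + W, :]
        return cols.reshape(B * H * W, 9 * C)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        self._shape = x.shape
        self._cols = self._im2col(x)
        out = self._buf.get("out", (B * H * W, self.w.shape[1]))
        np.matmul(self._cols, self.w, out=out)
        out += self.b
        return out.reshape(B, H, W, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        g = grad.reshape(B * H * W, -1)
        np.matmul(self._cols.T, g, out=self.dw)
        g.sum(axis=0, out=self.db)
        dcols = self._buf.get("dcols", (B * H * W, self.w.shape[0]))
        np.matmul(g, self.w.T, out=dcols)
        # adjoint of im2col: scatter-add the nine slabs back
        dxp = self._buf.get("dxp", (B, H + 2, W + 2, C))
        dxp.fill(0.0)
        dc = dcols.reshape(B, H, W, 9 * C)
        for k, (di, dj) in enumerate(_OFFSETS):
            dxp[:, di : di + H, dj : dj + W, :] += dc[:, :, :, k * C : (k + 1) * C]
        # hand back a contiguous buffer: strided views knock the GEMMs of
        # the next layer down off the BLAS fast path
        dx = self._buf.get("dx", (B, H, W, C))
        np.copyto(dx, dxp[:, 1 : 1 + H, 1 : 1 + W, :])
        return dx

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x):
        np.maximum(x, 0.0, out=x)  # in place: the producing layer's buffer
        self._out = x
        return x

    def backward(self, grad):
        grad *= self._out > 0
        return grad

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pooling; on exact ties the gradient is split evenly."""

    def __init__(self):
        self._buf = _Buffers()

    def forward(self, x):
        B, H, W, C = x.shape
        self._shape = x.shape
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
        out = self._buf.get("out", (B, H // 2, W // 2, C))
        xr.max(axis=(2, 4), out=out)
        mask = self._buf.get("mask", xr.shape, dtype=bool)
        np.equal(xr, out.reshape(B, H // 2, 1, W // 2, 1, C), out=mask)
        self._mask = mask
        inv = self._buf.get("inv", (B, H // 2, 1, W // 2, 1, C))
        mask.sum(axis=(2, 4), keepdims=True, out=inv.view(np.float32))
        np.divide(1.0, inv, out=inv)
        self._inv = inv
        return out

    def backward(self, grad):
        B, H, W, C = self._shape
        g = grad.reshape(B, H // 2, 1, W // 2, 1, C)
        dx = self._buf.get("dx", self._mask.shape)
        np.multiply(self._mask, g, out=dx)
        dx *= self._inv
        return dx.reshape(B, H, W, C)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        np.matmul(self._x.T, grad, out=self.dw)
        grad.sum(axis=0, out=self.db)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def params(self):
        return []


class SmallCNN:
    """Conv(3x3)+pool stack followed by two dense layers and a softmax.

    ``conv_filters`` gives the filter count of each conv block; each
    block halves the spatial dimensions through 2x2 max pooling.
    """

    def __init__(
        self,
        input_hw: int = 64,
        conv_filters: tuple[int, ...] = (32, 64, 128),
        dense_hidden: int = 128,
        n_out: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.input_hw = input_hw
        self.conv_filters = tuple(conv_filters)
        self.dense_hidden = dense_hidden
        self.n_out = n_out
        self.layers = []
        c_in, hw = 1, input_hw
        for c_out in conv_filters:
            self.layers += [_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()]
            c_in, hw = c_out, hw // 2
        self.layers += [
            _Flatten(),
            _Dense(hw * hw * c_in, dense_hidden, rng),
            _ReLU(),
            _Dense(dense_hidden, n_out, rng),
        ]
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- inference ----------------------------------------------------------

    def logits(self, crops: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(crops, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, :, :, None]  # add the channel axis (channels-last)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, crops: np.ndarray, batch_size: int = 64) -> np.ndarray:
        crops = np.asarray(crops, dtype=np.float32)
        out = np.empty((len(crops), self.n_out), dtype=np.float32)
        for i in range(0, len(crops), batch_size):
            out[i : i + batch_size] = softmax(self.logits(crops[i : i + batch_size]))
        return out

    # -- training -----------------------------------------------------------

    def train_step(self, crops: np.ndarray, labels: np.ndarray, lr: float = 1e-3) -> float:
        """One minibatch update; returns the loss.  The pre-update batch
        probabilities stay available as ``last_probs`` (for monitoring)."""
        probs = softmax(self.logits(crops))
        self.last_probs = probs
        loss = cross_entropy(probs, labels)
        grad = probs.copy()
        grad[np.arange(len(labels)), labels] -= 1.0
        grad /= len(labels)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        self._adam_update(lr)
        return loss

    def _adam_update(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self.layers:
            for _, param, grad in layer.params():
                if i not in self._adam_state:
                    self._adam_state[i] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self._adam_state[i]
                m += (1 - beta1) * (grad - m)
                v += (1 - beta2) * (grad * grad - v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                state[f"layer{li}.{name}"] = param.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                param[...] = state[f"layer{li}.{name}"]
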
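"""Minimal deterministic CNN in numpy with an RMSProp optimizer.

No deep-learning framework is a dependency of this package; the patch
classifier only needs a few convolution blocks on small binary images, and a
plain numpy implementation keeps training bit-reproducible given a seed and
a fixed BLAS thread count.

Layers: 3x3 same-padding convolution, ReLU, 2x2 max pooling, global average
pooling, dense.  Loss: binary cross-entropy on a single logit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "RMSProp", "ARCHITECTURES"]


class _Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (same spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._xp = None

    @property
    def params(self):
        return [("W", self.W, True), ("b", self.b, False)]

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        y = np.zeros((n, self.W.shape[0], h, w), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                y += np.einsum(
                    "oc,nchw->nohw",
                    self.W[:, :, di, dj],
                    xp[:, :, di : di + h, dj : dj + w],
                    optimize=True,
                )
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        xp = self._xp
        n, _, h, w = dy.shape
        dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di : di + h, dj : dj + w]
                dW[:, :, di, dj] = np.einsum(
                    "nohw,nchw->oc", dy, xs, optimize=True
                )
                dxp[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "oc,nohw->nchw", self.W[:, :, di, dj], dy, optimize=True
                )
        self.dW = dW
        self.db = dy.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    params = []
    grads = []

    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class _MaxPool2:
    """2x2 max pooling; ties resolve to the first maximal position."""

    params = []
    grads = []

    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class _GlobalAvgPool:
    params = []
    grads = []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class _Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    @property
    def params(self):
        return [("W", self.W, True), ("b", self.b, False)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W

    @property
    def grads(self):
        return [self.dW, self.db]


# channel progressions; each conv block is Conv3x3 -> ReLU -> MaxPool2 except
# the last which feeds global average pooling
ARCHITECTURES = {
    "small_cnn": (8, 16, 32),
    "deepflow_like": (16, 32, 64, 64),
}


class SmallCNN:
    """Sequential conv net mapping (N, 2, H, W) binary patches to one logit."""

    def __init__(self, channels=(8, 16, 32), c_in: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.layers = []
        prev = c_in
        for i, c in enumerate(channels):
            self.layers.append(_Conv3x3(prev, c, rng))
            self.layers.append(_ReLU())
            if i < len(channels) - 1:
                self.layers.append(_MaxPool2())
            prev = c
        self.layers.append(_GlobalAvgPool())
        self.layers.append(_Dense(prev, 1, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]  # logits

    def backward(self, dlogit: np.ndarray) -> None:
        dy = dlogit[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = np.empty(len(x))
        for i in range(0, len(x), batch):
            z = self.forward(np.asarray(x[i : i + batch], dtype=np.float32))
            out[i : i + batch] = 1.0 / (1.0 + np.exp(-z))
        return out

    # --- parameter access -------------------------------------------------
    def parameters(self):
        """Yield (layer, name, array, decay_flag) for all trainable params."""
        for layer in self.layers:
            for name, arr, decay in layer.params:
                yield layer, name, arr, decay

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr, _ in layer.params:
                out[f"layer{i}_{name}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr, _ in layer.params:
                arr[...] = state[f"layer{i}_{name}"]


class RMSProp:
    """RMSProp with coupled L2 weight decay and a step-decay LR schedule.

    The squared-gradient running average uses decay ``rho``; weight decay is
    added to the raw gradient before the cache update (as in classic MXNet
    RMSProp); the learning rate is multiplied by ``lr_factor`` every
    ``factor_epoch`` epochs.
    """

    def __init__(
        self,
        net: SmallCNN,
        learning_rate: float = 5e-4,
        weight_decay: float = 0.01,
        lr_factor: float = 0.25,
        factor_epoch: int = 10,
        rho: float = 0.9,
        eps: float = 1e-8,
    ):
        self.net = net
        self.lr0 = learning_rate
        self.weight_decay = weight_decay
        self.lr_factor = lr_factor
        self.factor_epoch = factor_epoch
        self.rho = rho
        self.eps = eps
        self._cache = [np.zeros_like(arr) for _, _, arr, _ in net.parameters()]

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.lr_factor ** (epoch // self.factor_epoch)

    def step(self, epoch: int) -> None:
        lr = self.lr_at(epoch)
        params = list(self.net.parameters())
        for (layer, _, arr, decay), cache, grad in zip(
            params, self._cache, (g for l in self.net.layers for g in l.grads)
        ):
            g = grad + (self.weight_decay * arr if decay else 0.0)
            cache *= self.rho
            cache += (1.0 - self.rho) * g * g
            arr -= lr * g / (np.sqrt(cache) + self.eps)
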
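"""A compact convolutional network in NumPy.

Implements exactly the pieces the motion classifier needs: 2D "same"
convolution, rectified-linear units, max pooling along the time axis
only, inverted dropout, a fully connected head with softmax cross-entropy,
and stochastic gradient descent with momentum (SGDM).  Forward and
backward passes are explicit; convolutions are evaluated as a sum of nine
shifted matrix products, which is fast for 3x3 kernels on CPU.

Arrays are (N, T, F, C): batch, time bins, frequency columns, channels.
All parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvBlock", "Dense", "Dropout", "Network", "sgdm_update",
           "softmax", "cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


class ConvBlock:
    """same-padded KxK convolution -> ReLU -> max pool (time axis, window 2).

    When the incoming time extent is 1 the pool degrades to a window of 1
    (identity), so any positive time extent survives five blocks.
    """

    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        self.W = (rng.standard_normal((kh, kw, in_ch, filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.kernel = kernel

    def params(self):
        return {"W": self.W, "b": self.b}

    def set_params(self, p):
        self.W, self.b = p["W"], p["b"]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        n, t, f, c = x.shape
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        y = np.empty((n, t, f, self.W.shape[3]), dtype=np.float32)
        y[:] = self.b
        for i in range(kh):
            for j in range(kw):
                y += xp[:, i:i + t, j:j + f, :] @ self.W[i, j]
        self._x, self._xp_shape = x, xp.shape
        # ReLU
        self._pre_relu_mask = y > 0
        y *= self._pre_relu_mask
        # time-axis max pool, window min(2, t), stride = window
        if t >= 2:
            t2 = t // 2
            yc = y[:, : 2 * t2].reshape(n, t2, 2, f, -1)
            self._arg = yc.argmax(axis=2)
            out = yc.max(axis=2)
            self._pool_in_t = t
        else:
            self._arg = None
            out = y
            self._pool_in_t = t
        return out

    def backward(self, dout: np.ndarray):
        n, t2, f, F = dout.shape
        t = self._pool_in_t
        if self._arg is not None:
            dy = np.zeros((n, t, f, F), dtype=np.float32)
            dyc = dy[:, : 2 * t2].reshape(n, t2, 2, f, F)
            idx = np.indices((n, t2, f, F))
            dyc[idx[0], idx[1], self._arg, idx[2], idx[3]] = dout
        else:
            dy = dout
        dy = dy * self._pre_relu_mask
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        x = self._x
        nb, tb, fb, cb = x.shape
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        dW = np.empty_like(self.W)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + tb, j:j + fb, :]
                dW[i, j] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
        db = dy.sum(axis=(0, 1, 2))
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + tb, j:j + fb, :] += dy @ self.W[i, j].T
        dx = dxp[:, ph:ph + tb, pw:pw + fb, :]
        return dx, {"W": dW, "b": db}


class Dropout:
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return {}

    def set_params(self, p):
        pass

    def forward(self, x, train: bool, rng: np.random.Generator | None = None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout, {}
        return dout * self._mask, {}


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((in_dim, out_dim))
                  * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def set_params(self, p):
        self.W, self.b = p["W"], p["b"]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        return dx, {"W": dW, "b": db}


class Network:
    """conv blocks -> dropout -> flatten -> dense -> softmax over classes."""

    def __init__(self, input_shape: tuple[int, int, int],
                 conv_filters: tuple[int, ...], kernel: tuple[int, int],
                 dropout_rate: float, n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        t, f, c = input_shape
        if t < 1 or f < 1:
            raise ValueError(f"input shape {input_shape} has empty extent")
        self.input_shape = input_shape
        self.blocks: list[ConvBlock] = []
        ch = c
        for nf in conv_filters:
            self.blocks.append(ConvBlock(ch, nf, kernel, rng))
            ch = nf
            t = max(1, t // 2)
        self.dropout = Dropout(dropout_rate)
        self.flat_dim = t * f * ch
        self.head = Dense(self.flat_dim, n_classes, rng)
        self.n_classes = n_classes

    # ---- parameter plumbing -------------------------------------------
    def layers(self):
        return [*self.blocks, self.dropout, self.head]

    def get_params(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params().items()} for l in self.layers()]

    def set_params(self, params: list[dict[str, np.ndarray]]) -> None:
        for l, p in zip(self.layers(), params):
            l.set_params({k: v.copy() for k, v in p.items()})

    # ---- passes -------------------------------------------------------
    def forward_features(self, x: np.ndarray, n_blocks: int) -> np.ndarray:
        """Deterministic pass through the first ``n_blocks`` conv blocks."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        for blk in self.blocks[:n_blocks]:
            x = blk.forward(x, train=False)
        return x

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                start_block: int = 0) -> np.ndarray:
        """Class probabilities, shape (N, n_classes).

        ``start_block`` feeds ``x`` in at the given conv block (``x`` must
        then be the output of :meth:`forward_features`).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        for blk in self.blocks[start_block:]:
            x = blk.forward(x, train)
        x = self.dropout.forward(x, train, rng)
        self._flat_shape = x.shape
        x = x.reshape(len(x), -1)
        logits = self.head.forward(x, train)
        return softmax(logits)

    def backward(self, probs: np.ndarray, labels: np.ndarray,
                 stop_block: int = 0) -> list[dict]:
        """Gradients of mean cross-entropy; call right after forward(train=True).

        ``stop_block`` skips gradient computation below that conv block
        (their entries are empty dicts) — used when those layers are frozen.
        """
        n = len(labels)
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        dx, g_head = self.head.backward(dlogits.astype(np.float32))
        dx = dx.reshape(self._flat_shape)
        dx, _ = self.dropout.backward(dx)
        grads = [g_head]
        for blk in reversed(self.blocks[stop_block:]):
            dx, g = blk.backward(dx)
            grads.append(g)
        grads.reverse()  # conv(stop)..conv5, head
        # align with layers(): conv blocks, dropout (no params), head
        return [{}] * stop_block + grads[:-1] + [{}] + [grads[-1]]


def sgdm_update(params: list[dict], grads: list[dict], velocity: list[dict],
                lr: float, momentum: float, frozen: list[bool]) -> None:
    """In-place SGDM step, skipping frozen layers entirely."""
    for p, g, v, fr in zip(params, grads, velocity, frozen):
        if fr or not g:
            continue
        for k in p:
            v[k] = momentum * v.get(k, 0.0) - lr * g[k]
            p[k] += v[k].astype(p[k].dtype)
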
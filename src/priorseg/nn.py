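"""Minimal numpy building blocks for the 3D fully convolutional network.

Tensors are channel-last, shape (B, X, Y, Z, C), float32 by default
(float64 is supported so gradients can be verified by finite differences).
Convolutions are 'valid' (no padding, unit stride), evaluated as one
accumulating GEMM per filter offset; each layer caches what its backward
pass needs, so the intended usage is one ``forward`` followed by at most one
``backward`` per step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3D", "ELU", "BatchNorm", "Dropout", "DenseConnection", "glorot_uniform"]


def glorot_uniform(shape: tuple[int, ...], rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    """Glorot (Xavier) uniform initialization for a (Cout, Cin, k, k, k) filter."""
    cout, cin = shape[0], shape[1]
    receptive = int(np.prod(shape[2:])) if len(shape) > 2 else 1
    fan_in = cin * receptive
    fan_out = cout * receptive
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _contig_rows(x: np.ndarray) -> np.ndarray:
    """Flatten (B, X, Y, Z, C) (or a spatial slice of it) to contiguous (M, C) rows."""
    c = x.shape[-1]
    return np.ascontiguousarray(x).reshape(-1, c)


class Conv3D:
    """Valid 3D convolution (cross-correlation) with bias.

    Evaluated as k^3 accumulating GEMMs, one per filter offset: the offset's
    spatial slice of the input (a cheap contiguous copy) is multiplied by the
    (Cin, Cout) weight slab and added to the output.  For the thin channel
    widths used here this beats an im2col megamatrix by a wide margin, and
    the backward pass reuses the same primitive (the input gradient is a
    full convolution of the output gradient with the flipped filters).
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        self.k = int(k)
        self.W = glorot_uniform((cout, cin, k, k, k), rng, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def _offsets(self):
        k = self.k
        return ((i, j, l) for i in range(k) for j in range(k) for l in range(k))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cout, cin = self.W.shape[:2]
        if x.shape[-1] != cin:
            raise ValueError(f"conv expected {cin} input channels, got {x.shape[-1]}")
        if self.k == 1:
            out = x.reshape(-1, cin) @ self.W.reshape(cout, cin).T + self.b
            out_shape = x.shape[:-1] + (cout,)
        else:
            if min(x.shape[1:4]) < self.k:
                raise ValueError(f"input spatial side {x.shape[1:4]} smaller than kernel {self.k}")
            b, X, Y, Z = x.shape[:4]
            s0, s1, s2 = X - self.k + 1, Y - self.k + 1, Z - self.k + 1
            out = np.zeros((b * s0 * s1 * s2, cout), dtype=x.dtype)
            for i, j, l in self._offsets():
                xs = _contig_rows(x[:, i : i + s0, j : j + s1, l : l + s2, :])
                out += xs @ self.W[:, :, i, j, l].T
            out += self.b
            out_shape = (b, s0, s1, s2, cout)
        if training:
            self._x = x
        return out.reshape(out_shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called before a training-mode forward")
        cout, cin = self.W.shape[:2]
        dy_mat = dy.reshape(-1, cout)
        self.db[...] = dy_mat.sum(axis=0)
        if self.k == 1:
            x_mat = x.reshape(-1, cin)
            self.dW[...] = (dy_mat.T @ x_mat).reshape(self.W.shape)
            dx = (dy_mat @ self.W.reshape(cout, cin)).reshape(x.shape)
            self._x = None
            return dx
        b, X, Y, Z = x.shape[:4]
        s0, s1, s2 = dy.shape[1:4]
        # filter gradient: one (Cout x M) @ (M x Cin) GEMM per offset
        for i, j, l in self._offsets():
            xs = _contig_rows(x[:, i : i + s0, j : j + s1, l : l + s2, :])
            self.dW[:, :, i, j, l] = dy_mat.T @ xs
        # input gradient: full convolution of padded dy with flipped filters
        p = self.k - 1
        dy_p = np.pad(dy, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        dx = np.zeros((b * X * Y * Z, cin), dtype=x.dtype)
        for i, j, l in self._offsets():
            ds = _contig_rows(dy_p[:, i : i + X, j : j + Y, l : l + Z, :])
            dx += ds @ self.W[:, :, p - i, p - j, p - l]
        self._x = None
        return dx.reshape(x.shape)


class ELU:
    """Exponential linear unit, shape parameter 1."""

    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        # d/dx elu(x) = 1 for x > 0, exp(x) = y + 1 otherwise
        dx = dy * np.where(y > 0, np.ones((), dtype=y.dtype), y + 1)
        self._y = None
        return dx


class BatchNorm:
    """Batch normalization over (batch, spatial) per channel.

    Training uses batch statistics and updates exponential running averages
    (momentum 0.9); inference uses the running statistics, making evaluation
    deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        if training:
            self._cache = (xhat, inv_sd.astype(x.dtype))
        return (self.gamma * xhat + self.beta).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._cache
        axes = tuple(range(dy.ndim - 1))
        m = dy.size // dy.shape[-1]
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = inv_sd / m * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(dy.dtype)


class Dropout:
    """Inverted dropout; active only when ``training`` and given an rng."""

    def __init__(self, p: float = 0.1):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class DenseConnection:
    """Channel-wise concatenation of centrally cropped feature maps.

    The trunk's conv outputs shrink by two voxels per layer; only the central
    ``out_side`` cube of each is concatenated, giving the classifier head
    simultaneous access to features from every depth.
    """

    def __init__(self, out_side: int):
        self.out_side = out_side
        self._shapes: list[tuple[int, ...]] | None = None

    @staticmethod
    def _crop_slices(side: int, out_side: int) -> tuple[slice, slice, slice]:
        off = (side - out_side) // 2
        sl = slice(off, off + out_side)
        return (sl, sl, sl)

    def forward(self, feature_maps: list[np.ndarray], training: bool = False) -> np.ndarray:
        crops = []
        for fm in feature_maps:
            sl = self._crop_slices(fm.shape[1], self.out_side)
            crops.append(fm[:, sl[0], sl[1], sl[2], :])
        if training:
            self._shapes = [fm.shape for fm in feature_maps]
        return np.concatenate(crops, axis=-1)

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        grads = []
        start = 0
        for shape in self._shapes:
            c = shape[-1]
            g = np.zeros(shape, dtype=dy.dtype)
            sl = self._crop_slices(shape[1], self.out_side)
            g[:, sl[0], sl[1], sl[2], :] = dy[..., start : start + c]
            grads.append(g)
            start += c
        self._shapes = None
        return grads
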
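"""Layer primitives with explicit forward/backward passes.

Three trainable layers cover the three network classes: ``Dense`` (fully
connected), ``Conv1D`` (one shared filter bank slid along the marker axis)
and ``LocalConv1D`` (the local convolutional layer: same windowing as a
convolution, but every window owns its own weights and intercept).  Windows
read positions ``s*w .. s*w + k - 1``; trailing markers beyond the last full
window are dropped ("valid" rule).

Parameters are initialized with a seeded Glorot-uniform scheme; gradients
are returned in the same order as ``params`` so an optimizer can zip them.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1D", "LocalConv1D", "n_windows", "relu"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def n_windows(p: int, kernel_size: int, stride: int) -> int:
    """Number of full windows of size k at stride s over p inputs."""
    if kernel_size < 1 or stride < 1:
        raise ValueError("kernel_size and stride must be positive")
    if p < kernel_size:
        raise ValueError(f"input length {p} shorter than kernel {kernel_size}")
    return (p - kernel_size) // stride + 1


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Affine layer X @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in < 1 or n_out < 1:
            raise ValueError("invalid Dense layer sizes")
        self.n_in, self.n_out = n_in, n_out
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self._X: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def n_weights(self) -> int:
        return self.W.size

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._X = X
        return X @ self.W + self.b

    def backward(self, dY: np.ndarray):
        X = self._X
        return dY @ self.W.T, [X.T @ dY, dY.sum(axis=0)]


class _Windowed:
    """Shared windowing for (local) convolutions over the marker axis."""

    def __init__(self, p: int, kernel_size: int, stride: int):
        self.p = p
        self.kernel_size = kernel_size
        self.stride = stride
        self.n_windows = n_windows(p, kernel_size, stride)
        starts = np.arange(self.n_windows) * stride
        self._gather = starts[:, None] + np.arange(kernel_size)[None, :]

    def _windows(self, X: np.ndarray) -> np.ndarray:
        """(batch, n_windows, k) view-by-gather of the input."""
        return X[:, self._gather]

    def _scatter(self, dXw: np.ndarray) -> np.ndarray:
        """Accumulate window gradients back onto the p input positions."""
        B = dXw.shape[0]
        dX = np.zeros((B, self.p))
        if self.stride == self.kernel_size:  # non-overlapping fast path
            span = self.n_windows * self.kernel_size
            dX[:, :span] = dXw.reshape(B, span)
        else:
            np.add.at(dX, (np.arange(B)[:, None, None], self._gather[None]), dXw)
        return dX


class LocalConv1D(_Windowed):
    """Local convolutional layer: per-window weights (n_windows x k) and
    per-window intercepts — the weight-untied generalization of Conv1D."""

    def __init__(self, p: int, kernel_size: int, stride: int,
                 rng: np.random.Generator):
        super().__init__(p, kernel_size, stride)
        self.W = _glorot(rng, (self.n_windows, kernel_size), kernel_size, 1)
        self.b = np.zeros(self.n_windows)
        self._Xw: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def n_weights(self) -> int:
        return self.W.size

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    @property
    def n_out(self) -> int:
        return self.n_windows

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        Xw = self._windows(X)
        if cache:
            self._Xw = Xw
        return np.einsum("bwk,wk->bw", Xw, self.W) + self.b

    def backward(self, dY: np.ndarray):
        Xw = self._Xw
        dW = np.einsum("bw,bwk->wk", dY, Xw)
        db = dY.sum(axis=0)
        dXw = dY[:, :, None] * self.W[None]
        return self._scatter(dXw), [dW, db]


class Conv1D(_Windowed):
    """1-D convolution: ``n_filters`` shared filters of length k, one
    intercept per filter; output flattened to (batch, n_windows * n_filters)."""

    def __init__(self, p: int, kernel_size: int, stride: int,
                 n_filters: int, rng: np.random.Generator):
        super().__init__(p, kernel_size, stride)
        if n_filters < 1:
            raise ValueError("n_filters must be positive")
        self.n_filters = n_filters
        self.F = _glorot(rng, (n_filters, kernel_size), kernel_size, 1)
        self.b = np.zeros(n_filters)
        self._Xw: np.ndarray | None = None

    @property
    def params(self):
        return [self.F, self.b]

    @property
    def n_weights(self) -> int:
        return self.F.size

    @property
    def n_params(self) -> int:
        return self.F.size + self.b.size

    @property
    def n_out(self) -> int:
        return self.n_windows * self.n_filters

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        Xw = self._windows(X)
        if cache:
            self._Xw = Xw
        Y = np.einsum("bwk,fk->bwf", Xw, self.F) + self.b
        return Y.reshape(X.shape[0], self.n_out)

    def backward(self, dY: np.ndarray):
        B = dY.shape[0]
        dYw = dY.reshape(B, self.n_windows, self.n_filters)
        dF = np.einsum("bwf,bwk->fk", dYw, self._Xw)
        db = dYw.sum(axis=(0, 1))
        dXw = np.einsum("bwf,fk->bwk", dYw, self.F)
        return self._scatter(dXw), [dF, db]
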
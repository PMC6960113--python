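"""Minimal 3D convolutional-network engine on numpy.

Implements exactly the pieces the age-regression CNN needs — 3x3x3
convolution (stride 1, padding 1), 3D batch normalization, ReLU, 2x2x2 max
pooling (stride 2, floor truncation of odd dims), fully connected layers,
mean-absolute-error loss, and SGD with momentum and weight decay — with
explicit forward/backward passes.

Volumes are carried channels-last, ``(batch, depth, height, width,
channels)``: the im2col matrix for a convolution can then be assembled from
27 contiguous slice copies and consumed by a single BLAS matmul, which is
what keeps a pure-numpy network trainable at desk scale on one CPU.

Correctness of every backward pass is pinned down by finite-difference
gradient checks in the test suite (run in float64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


@dataclass
class Param:
    """One trainable tensor with its gradient and weight-decay eligibility."""

    value: np.ndarray
    grad: np.ndarray | None = None
    decay: bool = True  # weight decay applies to conv/FC weights only
    velocity: np.ndarray | None = field(default=None, repr=False)


class Layer:
    params: list[Param]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    """He (fan-in, ReLU-gain) normal initialization: sd = sqrt(2 / fan_in)."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, padding 1 (spatial size preserved).

    Evaluated as a 27-tap stencil: for each kernel offset, a shifted view of
    the padded input is multiplied against the (c_in, c_out) weight slice and
    accumulated.  This avoids materializing the full im2col matrix (which is
    memory-traffic-bound on one core) while still running every product
    through BLAS.  Weights are stored flat as (27 * c_in, c_out),
    offset-major then input channel.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 27
        self.w = Param(he_normal(rng, fan_in, (fan_in, c_out), dtype), decay=True)
        self.b = Param(np.zeros(c_out, dtype=dtype), decay=False)
        self.params = [self.w, self.b]
        self._xp: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, d, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        nv = n * d * h * w
        out = np.empty((nv, self.c_out), dtype=x.dtype)
        out[:] = self.b.value
        wv = self.w.value
        for o, (i, j, k) in enumerate(_OFFSETS):
            xs = xp[:, i : i + d, j : j + h, k : k + w, :].reshape(nv, c)
            out += xs @ wv[o * c : (o + 1) * c]
        if train:
            self._xp, self._shape = xp, x.shape
        return out.reshape(n, d, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xp is not None and self._shape is not None
        n, d, h, w, c = self._shape
        nv = n * d * h * w
        gf = grad.reshape(nv, self.c_out)
        wv = self.w.value
        dw = np.empty_like(wv, dtype=grad.dtype)
        dxp = np.zeros_like(self._xp)
        for o, (i, j, k) in enumerate(_OFFSETS):
            xs = self._xp[:, i : i + d, j : j + h, k : k + w, :].reshape(nv, c)
            dw[o * c : (o + 1) * c] = xs.T @ gf
            dxp[:, i : i + d, j : j + h, k : k + w, :] += (
                gf @ wv[o * c : (o + 1) * c].T
            ).reshape(n, d, h, w, c)
        self.w.grad = dw
        self.b.grad = gf.sum(axis=0)
        self._xp = None
        return dxp[:, 1 : 1 + d, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, depth, height, width)."""

    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(c, dtype=dtype), decay=False)
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.last_batch_mean: np.ndarray | None = None
        self.last_batch_var: np.ndarray | None = None
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            # E[x^2] - E[x]^2 with float64 accumulation; avoids the full
            # float64 temporary np.var would allocate
            var = np.square(x).mean(axis=axes, dtype=np.float64) - mean**2
            np.clip(var, 0.0, None, out=var)
            self.last_batch_mean, self.last_batch_var = mean, var
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)) * invstd
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, invstd = self._cache
        axes = (0, 1, 2, 3)
        self.gamma.grad = (grad * xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * invstd
        self._cache = None
        return dx.astype(grad.dtype)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2; odd trailing voxels are dropped.

    The backward pass routes the gradient through an equality mask
    (``x == window max``); an exact tie inside one window would send the
    gradient to every tied voxel, a valid subgradient that in practice never
    triggers on continuous activations.
    """

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, d, h, w, c = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if min(d2, h2, w2) < 1:
            raise ValueError(f"spatial dims {(d, h, w)} too small to pool")
        win = x[:, : d2 * 2, : h2 * 2, : w2 * 2, :].reshape(
            n, d2, 2, h2, 2, w2, 2, c
        )
        out = win.max(axis=(2, 4, 6))
        if train:
            self._cache = (x, out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, out = self._cache
        n, d, h, w, c = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        win = x[:, : d2 * 2, : h2 * 2, : w2 * 2, :].reshape(
            n, d2, 2, h2, 2, w2, 2, c
        )
        mask = win == out[:, :, None, :, None, :, None, :]
        dwin = mask * grad[:, :, None, :, None, :, None, :]
        dx = np.zeros_like(x)
        dx[:, : d2 * 2, : h2 * 2, : w2 * 2, :] = dwin.reshape(
            n, d2 * 2, h2 * 2, w2 * 2, c
        )
        self._cache = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32
    ) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(he_normal(rng, n_in, (n_in, n_out), dtype), decay=True)
        self.b = Param(np.zeros(n_out, dtype=dtype), decay=False)
        self.params = [self.w, self.b]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        out = grad @ self.w.value.T
        self._x = None
        return out


class Sequential:
    """Plain layer chain with explicit train/eval forward and backprop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameter and running-statistic arrays, for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}.param{j}"] = p.value
            if isinstance(layer, BatchNorm3d):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p.value = state[f"layer{i}.param{j}"].astype(p.value.dtype)
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = state[f"layer{i}.running_mean"].astype(
                    np.float64
                )
                layer.running_var = state[f"layer{i}.running_var"].astype(np.float64)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its subgradient w.r.t. the predictions."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff).astype(pred.dtype) / diff.size
    return loss, grad


class SGD:
    """Mini-batch gradient descent with momentum; weight decay hits conv/FC
    weights only, not biases or batch-norm parameters."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        for p in self.params:
            p.velocity = np.zeros_like(p.value)

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad.astype(p.value.dtype)
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            p.velocity = self.momentum * p.velocity + g
            p.value -= self.lr * p.velocity
            p.grad = None
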
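"""Minimal CNN building blocks with explicit forward/backward passes.

All layers operate on channel-first arrays: ``(N, C, H, W)`` for 2D and
``(N, C, H, W, D)`` for 3D. Gradients are computed by hand-written
backpropagation, which keeps intermediate activations and their gradients
addressable — the property class-activation mapping needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv",
    "ReLU",
    "MaxPool",
    "BatchNorm",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(shape, fan_in, rng):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, kernel: tuple[int, ...],
            pad: list[tuple[int, int]]) -> np.ndarray:
    """Patch matrix ``(N, P, C*K)`` for a same-padded stride-1 convolution
    (P spatial positions, K kernel taps); one contiguous copy, after which
    every pass is a BLAS matmul."""
    from numpy.lib.stride_tricks import sliding_window_view

    xp = np.pad(x, pad)
    sp = x.shape[2:]
    v = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + len(kernel))))
    nd = len(kernel)
    # (N, C, *sp, *k) -> (N, *sp, C, *k)
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    v = np.ascontiguousarray(np.transpose(v, order))
    N = x.shape[0]
    P = int(np.prod(sp))
    return v.reshape(N, P, -1)


class Conv(Layer):
    """N-dimensional convolution (cross-correlation), stride 1, 'same'
    padding, via im2col + matmul. The input gradient is the same-padded
    convolution of the output gradient with the channel-transposed,
    spatially flipped kernel (exact for odd kernels); layers marked
    ``is_input_layer`` skip it.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dims: int, rng=None, is_input_layer: bool = False):
        if rng is None:
            rng = np.random.default_rng(0)
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.dims = dims
        k = (kernel_size,) * dims
        self.kernel = k
        self.is_input_layer = is_input_layer
        fan_in = in_channels * int(np.prod(k))
        self.w = Param(_he_init((out_channels, in_channels) + k, fan_in, rng))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._pad = [(0, 0), (0, 0)] + [(s // 2, s // 2) for s in k]

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        N, C = x.shape[:2]
        sp = x.shape[2:]
        if len(sp) != self.dims or C != self.w.value.shape[1]:
            raise ValueError(
                f"Conv expects (N, {self.w.value.shape[1]}, ...) with {self.dims} "
                f"spatial axes, got shape {x.shape}"
            )
        O = self.w.value.shape[0]
        col = _im2col(x, self.kernel, self._pad)     # (N, P, C*K)
        out = col @ self.w.value.reshape(O, -1).T    # (N, P, O)
        out += self.b.value
        self._col = col
        self._sp = sp
        nd = self.dims
        return np.ascontiguousarray(
            np.moveaxis(out.reshape((N,) + sp + (O,)), 1 + nd, 1))

    def backward(self, dout):
        sp = self._sp
        N = dout.shape[0]
        O, C = self.w.value.shape[:2]
        P = int(np.prod(sp))
        d2 = np.ascontiguousarray(
            np.moveaxis(dout, 1, 1 + self.dims)).reshape(N, P, O)
        dw = np.tensordot(d2, self._col, axes=([0, 1], [0, 1]))  # (O, C*K)
        self.w.grad += dw.reshape(self.w.value.shape)
        self.b.grad += d2.sum(axis=(0, 1))
        self._col = None
        if self.is_input_layer:
            return None
        # input gradient: convolve d_out with the flipped, transposed kernel
        wflip = self.w.value
        for ax in range(2, 2 + self.dims):
            wflip = np.flip(wflip, axis=ax)
        wflip = np.ascontiguousarray(np.swapaxes(wflip, 0, 1))   # (C, O, *k)
        dcol = _im2col(np.ascontiguousarray(dout, dtype=np.float32),
                       self.kernel, self._pad)                    # (N, P, O*K)
        dx = dcol @ wflip.reshape(C, -1).T                        # (N, P, C)
        return np.ascontiguousarray(
            np.moveaxis(dx.reshape((N,) + sp + (C,)), 1 + self.dims, 1))


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool(Layer):
    """Max pooling with stride equal to pool size; trailing remainder dropped.

    Axes shorter than the pool size are pooled with size 1 (left unchanged),
    so deep stacks degrade gracefully on thin volumes.
    """

    def __init__(self, pool_size: int = 2):
        self.pool = pool_size

    def forward(self, x, training=False, rng=None):
        sp = x.shape[2:]
        pools = tuple(min(self.pool, s) for s in sp)
        out_sp = tuple(s // p for s, p in zip(sp, pools))
        crop = (slice(None), slice(None)) + tuple(
            slice(0, o * p) for o, p in zip(out_sp, pools))
        xc = x[crop]
        # split every spatial axis into (blocks, within-block)
        shape = list(x.shape[:2])
        for o, p in zip(out_sp, pools):
            shape.extend([o, p])
        xr = xc.reshape(shape)
        nd = len(sp)
        block_axes = tuple(2 + 2 * i for i in range(nd))
        within_axes = tuple(3 + 2 * i for i in range(nd))
        xt = np.transpose(xr, (0, 1) + block_axes + within_axes)
        P = int(np.prod(pools))
        flat = xt.reshape(x.shape[:2] + out_sp + (P,))
        idx = np.argmax(flat, axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._state = (x.shape, crop, shape, block_axes, within_axes, idx, P,
                       out_sp, pools)
        return out

    def backward(self, dout):
        x_shape, crop, shape, block_axes, within_axes, idx, P, out_sp, pools = \
            self._state
        dflat = np.zeros(x_shape[:2] + out_sp + (P,), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        nd = len(out_sp)
        xt_shape = x_shape[:2] + out_sp + pools
        dxt = dflat.reshape(xt_shape)
        inv = np.argsort((0, 1) + block_axes + within_axes)
        dxr = np.transpose(dxt, inv)
        dxc = dxr.reshape([x_shape[0], x_shape[1]] + [
            o * p for o, p in zip(out_sp, pools)])
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dx[crop] = dxc
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False, rng=None):
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu = self.running_mean
            var = self.running_var
        bs = self._bshape(x)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(bs)) * istd.reshape(bs)
        out = self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)
        self._state = (xhat, istd, axes, training)
        return out

    def backward(self, dout):
        xhat, istd, axes, training = self._state
        bs = self._bshape(dout)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(bs)
        if not training:
            return dxhat * istd.reshape(bs)
        m = dout.size / dout.shape[1]
        dx = (istd.reshape(bs) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(bs)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(bs)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.w = Param(_he_init((n_in, n_out), n_in, rng))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, training=False, rng=None, keep_outputs=False):
        outs = []
        for l in self.layers:
            x = l.forward(x, training=training, rng=rng)
            if keep_outputs:
                outs.append(x)
        if keep_outputs:
            self._outputs = outs
        return x

    def forward_from(self, start: int, a, training=False, rng=None):
        """Run layers ``start+1`` onward on activation ``a`` (the output of
        layer ``start``)."""
        for l in self.layers[start + 1:]:
            a = l.forward(a, training=training, rng=rng)
        return a

    def backward(self, dout, collect=False):
        """Backpropagate; with ``collect`` return the gradient w.r.t. every
        layer's output (index-aligned with ``self.layers``)."""
        grads = [None] * len(self.layers) if collect else None
        for i in range(len(self.layers) - 1, -1, -1):
            if collect:
                grads[i] = dout
            dout = self.layers[i].backward(dout)
        if collect:
            return dout, grads
        return dout
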
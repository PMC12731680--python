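"""Minimal numpy neural-network layers with explicit backward passes.

Feature maps are 5-axis ``(batch, channels, depth, height, width)``
float32 arrays, with depth the spectral axis. Convolutions are stride-1,
same-padded, dispatched to JIT-compiled direct kernels; the input
gradient of a same-padded stride-1 convolution is itself a same-padded
convolution with the spatially flipped, channel-transposed kernel, so
backward reuses the forward primitive.

Layers cache what they need during ``forward`` and must be stepped
backward in reverse call order.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from ._kernels import conv3d_grad_weight, conv3d_valid


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer: no parameters, identity bookkeeping."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad_same(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    kd, kh, kw = kernel
    return np.pad(x, ((0, 0), (0, 0), (kd // 2, kd // 2),
                      (kh // 2, kh // 2), (kw // 2, kw // 2)))


# Width below which the vectorized direct kernel loses to im2col + BLAS.
_DIRECT_MIN_WIDTH = 12


def _im2col(xp: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Unfold a padded map into ``(N*D*H*W, C*kd*kh*kw)`` patch rows."""
    d, h, w = out_shape
    windows = np.lib.stride_tricks.sliding_window_view(
        xp, (xp.shape[2] - d + 1, xp.shape[3] - h + 1, xp.shape[4] - w + 1),
        axis=(2, 3, 4))
    windows = windows.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    n = xp.shape[0]
    return np.ascontiguousarray(windows).reshape(n * d * h * w, -1)


def _conv_same(xp: np.ndarray, weight5: np.ndarray, bias: np.ndarray,
               out_shape: tuple[int, int, int]) -> np.ndarray:
    """Same-padded conv of a pre-padded input; picks the faster path."""
    if out_shape[2] >= _DIRECT_MIN_WIDTH:
        return conv3d_valid(xp, weight5, bias)
    n = xp.shape[0]
    o = weight5.shape[0]
    col = _im2col(xp, out_shape)
    out = col @ weight5.reshape(o, -1).T + bias
    return np.ascontiguousarray(
        out.reshape((n,) + out_shape + (o,)).transpose(0, 4, 1, 2, 3))


class Conv3d(Layer):
    """Stride-1, same-padded 3-D convolution (odd kernel sizes)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None):
        if any(k % 2 == 0 for k in kernel):
            raise ParameterError("convolution kernel sizes must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, in_channels) + self.kernel))
        self.bias = Parameter(np.zeros(out_channels))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = _pad_same(x, self.kernel)
        out = _conv_same(xp, self.weight.data, self.bias.data, x.shape[2:])
        if training:
            self._cache = (xp, x.shape[2:])
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, out_shape = self._cache
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        kd, kh, kw = self.kernel
        if out_shape[2] >= _DIRECT_MIN_WIDTH:
            gw, gb = conv3d_grad_weight(xp, grad, kd, kh, kw)
        else:
            col = _im2col(xp, out_shape)
            g_mat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_channels)
            gw = (g_mat.T @ col).reshape(self.weight.data.shape)
            gb = g_mat.sum(axis=0)
        self.weight.grad += gw.astype(np.float32)
        self.bias.grad += gb.astype(np.float32)
        # Input gradient: same-pad conv with the flipped, transposed kernel.
        w_flip = np.ascontiguousarray(
            self.weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        gx = _conv_same(_pad_same(grad, self.kernel), w_flip,
                        np.zeros(self.in_channels, dtype=np.float32),
                        out_shape)
        self._cache = None
        return gx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        mean_b = mean.reshape(1, -1, 1, 1, 1)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        inv_b = inv_std.reshape(1, -1, 1, 1, 1)
        x_hat = (x - mean_b) * inv_b
        out = self.gamma.data.reshape(1, -1, 1, 1, 1) * x_hat \
            + self.beta.data.reshape(1, -1, 1, 1, 1)
        if training:
            self._cache = (x_hat, inv_std)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.gamma.grad += (grad * x_hat).sum(axis=axes).astype(np.float32)
        self.beta.grad += grad.sum(axis=axes).astype(np.float32)
        g = self.gamma.data.reshape(1, -1, 1, 1, 1)
        inv_b = inv_std.reshape(1, -1, 1, 1, 1)
        sum_g = grad.sum(axis=axes, keepdims=True)
        sum_gx = (grad * x_hat).sum(axis=axes, keepdims=True)
        gx = g * inv_b * (grad - sum_g / m - x_hat * sum_gx / m)
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = grad * self._mask
        self._mask = None
        return gx


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._out = out if training else None
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = grad * self._out * (1.0 - self._out)
        self._out = None
        return gx.astype(np.float32)


class MaxPool3d(Layer):
    """Non-overlapping max pooling; dims must divide the pool factors."""

    def __init__(self, pool: tuple[int, int, int] = (1, 2, 2)):
        self.pool = tuple(pool)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pd, ph, pw = self.pool
        n, c, d, h, w = x.shape
        if d % pd or h % ph or w % pw:
            raise ParameterError(
                f"feature map {x.shape[2:]} not divisible by pool {self.pool}")
        xr = x.reshape(n, c, d // pd, pd, h // ph, ph, w // pw, pw)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // pd, h // ph, w // pw, pd * ph * pw)
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        pd, ph, pw = self.pool
        n, c, d, h, w = x_shape
        gx = np.zeros((n, c, d // pd, h // ph, w // pw, pd * ph * pw),
                      dtype=np.float32)
        np.put_along_axis(gx, idx[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, d // pd, h // ph, w // pw, pd, ph, pw)
        gx = gx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        self._cache = None
        return np.ascontiguousarray(gx)


class Upsample3d(Layer):
    """Nearest-neighbour upsampling by integer factors."""

    def __init__(self, factor: tuple[int, int, int] = (1, 2, 2)):
        self.factor = tuple(factor)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        fd, fh, fw = self.factor
        out = x
        if fd > 1:
            out = np.repeat(out, fd, axis=2)
        if fh > 1:
            out = np.repeat(out, fh, axis=3)
        if fw > 1:
            out = np.repeat(out, fw, axis=4)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        fd, fh, fw = self.factor
        n, c, d, h, w = grad.shape
        gr = grad.reshape(n, c, d // fd, fd, h // fh, fh, w // fw, fw)
        return np.ascontiguousarray(gr.sum(axis=(3, 5, 7)))


class SpectralCollapse(Layer):
    """Head that collapses channels and the full spectral depth to one map.

    A linear map over the (channel, depth) axes at each spatial location —
    equivalently a valid convolution whose kernel spans the entire
    remaining spectral depth — producing an ``(N, H, W)`` logit map.
    """

    def __init__(self, in_channels: int, depth: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * depth
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(in_channels, depth)))
        self.bias = Parameter(np.zeros(1))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.tensordot(x, self.weight.data, axes=([1, 2], [0, 1]))
        out = out + self.bias.data[0]
        if training:
            self._cache = x
        return out.astype(np.float32)  # (N, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += np.einsum("nhw,ncdhw->cd", grad, x,
                                      optimize=True).astype(np.float32)
        self.bias.grad += np.float32(grad.sum())
        gx = grad[:, None, None, :, :] * self.weight.data[None, :, :, None, None]
        self._cache = None
        return gx.astype(np.float32)
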
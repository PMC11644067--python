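"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "BatchNorm1d",
    "GELU",
    "ReLU",
    "Sequential",
    "Conv2d",
    "AvgPool2d",
    "GlobalAvgPool2d",
    "Flatten",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self.children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs = [v for k, v in self.__dict__.items()
                if isinstance(v, np.ndarray) and k.startswith("running_")]
        for child in self.children():
            bufs.extend(child.buffers())
        return bufs

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running state, in deterministic order."""
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = [p.data for p in self.parameters()] + self.buffers()
        if len(arrays) != len(targets):
            raise ValueError(
                f"state mismatch: expected {len(targets)} arrays, got {len(arrays)}"
            )
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expects width {self.in_features}, got {x.shape[-1]}"
            )
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch statistics in training mode, running statistics in eval mode."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2.0).mean(axis=0, keepdims=True)
            batch = x.shape[0]
            unbiased = var.data.reshape(-1) * (batch / max(batch - 1, 1))
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            x_hat = centered * ((var + self.eps) ** -0.5)
        else:
            x_hat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return x_hat * self.gamma + self.beta


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for module in self.modules:
            x = module(x)
        return x


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    strides = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(strides[0], strides[1], strides[2], strides[3],
                 strides[2] * stride, strides[3] * stride),
    )
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    x = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Conv2d(Module):
    """im2col convolution over NCHW input."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv2d expects NCHW with {self.in_channels} channels, got {x.shape}"
            )
        k, s, p = self.kernel_size, self.stride, self.padding
        n = x.shape[0]
        cols, oh, ow = _im2col(x.data, k, k, s, p)
        cols = np.ascontiguousarray(cols)
        w_mat = self.weight.data.reshape(self.out_channels, -1)
        out = np.matmul(w_mat, cols) + self.bias.data[None, :, None]
        out = out.reshape(n, self.out_channels, oh, ow)

        x_t, w_t, b_t = x, self.weight, self.bias
        x_shape = x.shape

        def backward(grad, cols=cols):
            g = grad.reshape(n, self.out_channels, -1)
            if b_t.requires_grad:
                b_t._accumulate(g.sum(axis=(0, 2)))
            if w_t.requires_grad:
                gw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
                w_t._accumulate(gw.reshape(w_t.shape))
            if x_t.requires_grad:
                gcols = np.matmul(w_mat.T, g)
                x_t._accumulate(_col2im(gcols, x_shape, k, k, s, p))

        return Tensor._from_op(out, (x_t, w_t, b_t), backward)


class AvgPool2d(Module):
    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"AvgPool2d({s}) on indivisible spatial dims {h}x{w}")
        return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
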
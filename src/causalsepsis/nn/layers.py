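"""Neural-network building blocks on top of the autodiff engine.

Layers mirror the usual deep-learning conventions: ``Conv1d``/``Conv2d`` via
im2col matrix multiplication, ``BatchNorm1d`` with running statistics for
deterministic eval-mode inference, max pooling, and fully connected layers.
Weight initialisation is fan-in scaled and driven by an explicit
``numpy.random.Generator`` so every network is reproducible from its seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Conv2d",
    "BatchNorm1d",
    "MLP",
    "max_pool1d",
    "max_pool2d",
]


def _fan_in_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal parameter container with recursive traversal."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for t in self._walk():
            if id(t) not in seen:
                seen.add(id(t))
                yield t

    def _walk(self) -> Iterator[Tensor]:
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v._walk()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item._walk()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state (de)serialisation --------------------------------------------
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                if v.data.shape != arrays[key].shape:
                    raise ValueError(
                        f"shape mismatch for {key}: expected {v.data.shape}, "
                        f"got {arrays[key].shape}"
                    )
                v.data = np.asarray(arrays[key])  # keep stored dtype
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(arrays[key]))
            elif isinstance(v, Module):
                v.load_state_arrays(arrays, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.asarray(arrays[f"{key}.{i}"], dtype=np.float64)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_fan_in_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(_fan_in_init(rng, (out_features,), in_features),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution over the last axis of an (N, C_in, L) input."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            _fan_in_init(rng, (out_channels, in_channels, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(_fan_in_init(rng, (out_channels,), fan_in), requires_grad=True)
        self.padding = padding
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels

    def __call__(self, x: Tensor) -> Tensor:
        xd, wd, bd = x.data, self.weight.data, self.bias.data
        n, cin, L = xd.shape
        if cin != self.in_channels:
            raise ValueError(
                f"Conv1d expected {self.in_channels} input channels, got {cin}"
            )
        k, p = self.kernel_size, self.padding
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p))) if p else xd
        l_out = xp.shape[-1] - k + 1
        # (N, Cin, l_out, k) -> (N, l_out, Cin*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, l_out, cin * k)
        wmat = wd.reshape(self.out_channels, cin * k)
        out = cols @ wmat.T + bd  # (N, l_out, Cout)
        out = out.transpose(0, 2, 1)

        x_t, w_t, b_t = x, self.weight, self.bias

        def back(g):
            gt = g.transpose(0, 2, 1)  # (N, l_out, Cout)
            gw = np.einsum("nlc,nlk->ck", gt, cols).reshape(wd.shape)
            gb = gt.sum(axis=(0, 1))
            dcols = (gt @ wmat).reshape(n, l_out, cin, k)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j:j + l_out] += dcols[:, :, :, j].transpose(0, 2, 1)
            dx = dxp[:, :, p:p + L] if p else dxp
            return dx, gw, gb

        return Tensor._make(out, (x_t, w_t, b_t), back)


class Conv2d(Module):
    """Valid 2-D convolution on (N, C_in, H, W) inputs."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _fan_in_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(_fan_in_init(rng, (out_channels,), fan_in), requires_grad=True)
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels

    def __call__(self, x: Tensor) -> Tensor:
        xd, wd, bd = x.data, self.weight.data, self.bias.data
        n, cin, H, W = xd.shape
        k = self.kernel_size
        ho, wo = H - k + 1, W - k + 1
        win = np.lib.stride_tricks.sliding_window_view(xd, (k, k), axis=(-2, -1))
        # (N, Cin, ho, wo, k, k) -> (N, ho*wo, Cin*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, cin * k * k
        )
        wmat = wd.reshape(self.out_channels, cin * k * k)
        out = (cols @ wmat.T + bd).transpose(0, 2, 1).reshape(n, self.out_channels, ho, wo)

        def back(g):
            gt = g.reshape(n, self.out_channels, ho * wo).transpose(0, 2, 1)
            gw = np.einsum("nlc,nlk->ck", gt, cols).reshape(wd.shape)
            gb = gt.sum(axis=(0, 1))
            dcols = (gt @ wmat).reshape(n, ho, wo, cin, k, k)
            dx = np.zeros_like(xd)
            for di in range(k):
                for dj in range(k):
                    dx[:, :, di:di + ho, dj:dj + wo] += dcols[:, :, :, :, di, dj].transpose(
                        0, 3, 1, 2
                    )
            return dx, gw, gb

        return Tensor._make(out, (x, self.weight, self.bias), back)


def max_pool1d(x: Tensor, kernel: int = 2) -> Tensor:
    n, c, L = x.shape
    if L % kernel:
        raise ValueError(f"length {L} not divisible by pool kernel {kernel}")
    return x.reshape(n, c, L // kernel, kernel).max_last()


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    n, c, H, W = x.shape
    if H % kernel or W % kernel:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool kernel {kernel}")
    h2, w2 = H // kernel, W // kernel
    x = x.reshape(n, c, h2, kernel, w2, kernel)
    x = x.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, kernel * kernel)
    return x.max_last()


class BatchNorm1d(Module):
    """Per-channel batch normalisation for (N, C, L) tensors.

    Training mode normalises by batch statistics and updates exponential
    running averages; eval mode uses the running statistics only, so
    eval-mode outputs are invariant to batch composition.
    """

    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, num_channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_channels, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, num_channels, 1))
        self.running_var = np.ones((1, num_channels, 1))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return self.gamma * xhat + self.beta


class MLP(Module):
    """Fully connected stack with tanh hidden activations."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "tanh", final_activation: bool = False):
        super().__init__()
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.activation = activation
        self.final_activation = final_activation

    def _act(self, x: Tensor) -> Tensor:
        return x.relu() if self.activation == "relu" else x.tanh()

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = self._act(x)
        return x
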
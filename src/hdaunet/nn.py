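"""Layer/module framework on top of the autodiff engine.

Provides the building blocks of the dose-prediction architectures: plain 3D
convolutions, batch normalization, the dense convolution and dense
downsampling operations of hierarchically dense U-nets, and the additive
soft attention gate used on skip connections.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv3d, maxpool3d_2x, resample_trilinear

__all__ = [
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "DenseConv",
    "DenseDown",
    "AttentionGate",
]


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.buffers(prefix + cname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buffer:" + k: v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                bufs[key[len("buffer:") :]][...] = value
            else:
                params[key].data = value.copy()


class Conv3d(Module):
    """3D convolution, cubic kernel (1 or 3), 'same' padding, optional stride.

    Weights use He initialization (appropriate for the ReLU nonlinearities
    that follow every convolution here); biases start at zero.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels) + (kernel_size,) * 3)
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm3d(Module):
    """Per-channel batch normalization over the spatial axes (batch of one).

    Training mode normalizes with the current map's statistics and updates
    exponential running estimates; eval mode uses the running estimates, so
    inference is deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float64):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[0]
        if self.training:
            mu = x.mean(axis=(1, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(1, 2, 3), keepdims=True)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu.data.reshape(c)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(c, 1, 1, 1))
            var = Tensor(self.running_var.reshape(c, 1, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(c, 1, 1, 1) + self.beta.reshape(c, 1, 1, 1)


class DenseConv(Module):
    """Dense convolution: 3x3x3 conv (+optional batch norm) + ReLU, result
    concatenated onto the incoming features. Adds ``growth_rate`` channels
    while leaving the spatial extent unchanged."""

    def __init__(self, in_channels: int, growth_rate: int, batch_norm: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        self.conv = Conv3d(in_channels, growth_rate, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm3d(growth_rate, dtype=dtype) if batch_norm else None
        self.out_channels = in_channels + growth_rate

    def forward(self, x: Tensor) -> Tensor:
        new = self.conv(x)
        if self.bn is not None:
            new = self.bn(new)
        return concat([x, new.relu()], axis=0)


class DenseDown(Module):
    """Dense downsampling: a stride-2 3x3x3 conv branch (+optional batch
    norm, ReLU) concatenated with the incoming features max-pooled by 2.
    Halves each spatial axis (ceil) and adds ``growth_rate`` channels."""

    def __init__(self, in_channels: int, growth_rate: int, batch_norm: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        self.conv = Conv3d(in_channels, growth_rate, 3, stride=2, rng=rng, dtype=dtype)
        self.bn = BatchNorm3d(growth_rate, dtype=dtype) if batch_norm else None
        self.out_channels = in_channels + growth_rate

    def forward(self, x: Tensor) -> Tensor:
        new = self.conv(x)
        if self.bn is not None:
            new = self.bn(new)
        return concat([maxpool3d_2x(x), new.relu()], axis=0)


class AttentionGate(Module):
    """Additive soft attention gate on a skip connection.

    Skip and gating maps are each projected by a 1x1x1 convolution to
    ``inter_channels`` features, summed, passed through ReLU, projected to a
    single channel and squashed by a sigmoid into per-voxel coefficients
    alpha in [0, 1]. The gated output is the skip map scaled voxel-wise by
    alpha (broadcast across channels).
    """

    def __init__(self, skip_channels: int, gate_channels: int, inter_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        self.proj_skip = Conv3d(skip_channels, inter_channels, 1, rng=rng, dtype=dtype)
        self.proj_gate = Conv3d(gate_channels, inter_channels, 1, rng=rng, dtype=dtype)
        self.psi = Conv3d(inter_channels, 1, 1, rng=rng, dtype=dtype)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        if gate.shape[1:] != skip.shape[1:]:
            gate = resample_trilinear(gate, skip.shape[1:])
        mixed = (self.proj_skip(skip) + self.proj_gate(gate)).relu()
        return self.psi(mixed).sigmoid()

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)
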
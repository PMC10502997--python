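"""Neural network building blocks: modules, 3D convolution, batch norm, CBR."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, batch_norm, batch_norm_train, conv3d, conv_output_size


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
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

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_bn(""):
            state[f"{name}.running_mean"] = m.running_mean.copy()
            state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch loading {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for name, m in self._named_bn(""):
            m.running_mean = np.asarray(state[f"{name}.running_mean"]).copy()
            m.running_var = np.asarray(state[f"{name}.running_var"]).copy()

    def _named_bn(self, prefix: str) -> Iterator[tuple[str, "BatchNorm3d"]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, BatchNorm3d):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_bn(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        if isinstance(item, BatchNorm3d):
                            yield f"{full}.{i}", item
                        else:
                            yield from item._named_bn(f"{full}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution with explicit stride / padding / dilation triples.

    Records the spatial sizes of its last call in ``last_io`` so the whole
    network can be audited against the analytic output-size formula.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel,
                 stride=1, padding=0, dilation=1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.dilation = _triple(dilation)
        rng = rng or np.random.default_rng()
        fan_in = self.in_channels * int(np.prod(self.kernel))
        std = float(np.sqrt(2.0 / fan_in))  # He init for ReLU networks
        self.weight = Parameter(
            rng.normal(0.0, std, (self.out_channels, self.in_channels, *self.kernel)))
        self.bias = Parameter(np.zeros(self.out_channels)) if bias else None
        self.last_io: tuple[tuple[int, ...], tuple[int, ...]] | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        out = conv3d(x, self.weight, self.bias,
                     self.stride, self.padding, self.dilation)
        self.last_io = (tuple(x.shape[2:]), tuple(out.shape[2:]))
        return out

    def expected_output_spatial(self, in_spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(
            conv_output_size(i, k, s, p, d)
            for i, k, s, p, d in zip(in_spatial, self.kernel, self.stride,
                                     self.padding, self.dilation))


class BatchNorm3d(Module):
    """Per-channel batch normalization over (B, D, H, W).

    Training mode normalizes with mini-batch statistics and updates running
    estimates; eval mode uses the stored running statistics.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = int(num_features)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.astype(np.float32))
            return out
        inv_std = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        return batch_norm(x, self.gamma, self.beta,
                          self.running_mean.astype(x.dtype), inv_std)


class CBR(Module):
    """Convolution -> batch normalization -> ReLU composite block."""

    def __init__(self, in_channels: int, out_channels: int, kernel,
                 stride=1, padding=0, dilation=1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, kernel, stride=stride,
                           padding=padding, dilation=dilation, rng=rng)
        self.bn = BatchNorm3d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
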
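"""Neural-network building blocks: parameter containers and standard layers."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Linear", "Conv2d", "ConvTranspose2d", "LayerNorm",
    "Sequential", "GELU", "ReLU", "Sigmoid", "MultiHeadSelfAttention",
    "trunc_normal",
]


DTYPE = np.float32  # model parameters and activations run in single precision


def trunc_normal(rng: np.random.Generator, shape, sd: float | None = None,
                 fan_in: int | None = None) -> np.ndarray:
    """Truncated-normal init at +/- 2 sd.

    Without an explicit ``sd`` the scale is fan-in matched (sd = fan_in^-1/2),
    which keeps activation variance roughly constant through the narrow
    layers of the reduced-scale configuration.
    """
    if sd is None:
        if fan_in is None:
            fan_in = int(shape[0])
        sd = fan_in ** -0.5
    x = rng.normal(0.0, sd, size=shape)
    return np.clip(x, -2 * sd, 2 * sd).astype(DTYPE)


class Module:
    """Minimal parameter container with recursive traversal and state I/O."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:4]}")
        for k, v in params.items():
            v.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, sd: float | None = None):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (d_in, d_out), sd, fan_in=d_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int | tuple, rng,
                 stride: int | tuple = 1, padding: int | tuple = 0,
                 sd: float | None = None):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.weight = Tensor(trunc_normal(rng, (c_out, c_in, kh, kw), sd,
                                          fan_in=c_in * kh * kw),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 stride: int = 2, padding: int = 1, output_padding: int = 0,
                 sd: float | None = None):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (c_in, c_out, kernel, kernel), sd,
                                          fan_in=c_in * kernel * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, self.eps)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MultiHeadSelfAttention(Module):
    """Pre-softmax scaled dot-product self-attention over (B, T, C) tokens."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"heads ({n_heads}) must divide width ({dim})")
        self.dim, self.n_heads = dim, n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, c = x.shape
        h, dh = self.n_heads, c // self.n_heads
        qkv = self.qkv(x).reshape(b, t, 3, h, dh).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, H, T, dh)
        att = F.softmax(q @ k.transpose((0, 1, 3, 2)) * (dh ** -0.5), axis=-1)
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(b, t, c)
        return self.proj(out)
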
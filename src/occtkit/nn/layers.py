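"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        p = Tensor(data, requires_grad=True)
        self._params[name] = p
        setattr(self, name, p)
        return p

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data[...] = state[n]

    def __call__(self, x):
        return self.forward(x)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        super().__init__()
        self.add_param("w", glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.bias = bias
        if bias:
            self.add_param("b", np.zeros(n_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.bias else y


class Conv2d(Module):
    def __init__(self, rng, c_in: int, c_out: int, kernel: int,
                 stride: int = 1, padding=0, bias: bool = True):
        super().__init__()
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.add_param("w", glorot_uniform(rng, (c_out, c_in, kernel, kernel),
                                           fan_in, fan_out))
        self.bias = bias
        if bias:
            self.add_param("b", np.zeros(c_out, dtype=np.float32))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.w, self.b if self.bias else None,
                        stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-s transposed convolution (zero-dilated equivalent form)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 4,
                 stride: int = 2, padding: int = 1, bias: bool = True):
        super().__init__()
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.add_param("w", glorot_uniform(rng, (c_out, c_in, kernel, kernel),
                                           fan_in, fan_out))
        self.bias = bias
        if bias:
            self.add_param("b", np.zeros(c_out, dtype=np.float32))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.w, self.b if self.bias else None,
                                  stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.add_param("gamma", np.ones(dim, dtype=np.float32))
        self.add_param("beta", np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        xn = (x - mu) * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.add_param("gamma", np.ones(channels, dtype=np.float32))
        self.add_param("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        gamma = self.gamma.reshape(1, -1, 1, 1)
        beta = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) * (var + self.eps) ** -0.5
        return xn * gamma + beta


class Dropout(Module):
    """Inverted dropout with a module-local seeded RNG (noop in eval mode)."""

    def __init__(self, rng, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(rng.integers(0, 2 ** 63))

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = np.float32(1.0 - self.p)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep) * (1.0 / keep)
        return x * Tensor(mask.astype(np.float32))


class Activation(Module):
    def __init__(self, name: str):
        super().__init__()
        key = name.lower().replace("-", "_").replace("leakyrelu", "leaky_relu")
        if key not in F.ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}; "
                             f"choose from {sorted(F.ACTIVATIONS)}")
        self.name = key

    def forward(self, x: Tensor) -> Tensor:
        return F.ACTIVATIONS[self.name](x)


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, embed_dim: int, n_heads: int, dropout: float = 0.0):
        super().__init__()
        if embed_dim % n_heads != 0:
            raise ValueError(f"embed_dim {embed_dim} not divisible by "
                             f"n_heads {n_heads}")
        self.embed_dim, self.n_heads = embed_dim, n_heads
        self.head_dim = embed_dim // n_heads
        self.qkv = Dense(rng, embed_dim, 3 * embed_dim)
        self.proj = Dense(rng, embed_dim, embed_dim)
        self.drop = Dropout(rng, dropout)

    def forward(self, x: Tensor) -> Tensor:
        s, g, e = x.shape
        h, d = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(s, g, 3, h, d).transpose(2, 0, 3, 1, 4)
        q = qkv.reshape(3, s * h, g, d)
        # split via constant masks is wasteful; slice the stacked tensor instead
        q_, k_, v_ = _split_first(q)
        attn = F.softmax((q_ @ k_.transpose(0, 2, 1)) * (d ** -0.5), axis=-1)
        attn = self.drop(attn)
        out = (attn @ v_).reshape(s, h, g, d).transpose(0, 2, 1, 3).reshape(s, g, e)
        return self.proj(out)


def _split_first(t: Tensor):
    """Split a stacked tensor along its leading axis of size 3."""
    outs = []
    for i in range(3):
        data = t.data[i]

        def bw(g, i=i):
            full = np.zeros_like(t.data)
            full[i] = g
            t._accumulate(full)

        outs.append(t._make(data, (t,), bw))
    return outs


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
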
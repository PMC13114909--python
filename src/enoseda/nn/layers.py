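"""Neural-network building blocks on top of the autograd engine.

Modules mirror the familiar torch-style contract: ``parameters()`` /
``named_parameters()`` walk the module tree, ``train()``/``eval()`` toggle
stochastic layers and batch-norm statistics, and ``state_dict`` /
``load_state_dict`` move plain numpy arrays in and out.  Parameter
initialisation is fan-in uniform and driven entirely by the ``rng`` handed to
each constructor, so a model build is a pure function of its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class Module:
    def __init__(self):
        self.training = True

    # -- tree walking ---------------------------------------------------------
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
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and not val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.data.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) ^ set(d)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in own.items():
            if t.data.shape != d[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.asarray(d[k], dtype=t.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
            b = np.zeros(out_dim)
        else:
            w = _fan_in_uniform(rng, (in_dim, out_dim), in_dim)
            b = _fan_in_uniform(rng, (out_dim,), in_dim)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel
        self.weight = Tensor(_fan_in_uniform(rng, (out_ch, in_ch, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(_fan_in_uniform(rng, (out_ch,), fan_in), requires_grad=True)
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.padding)


class BatchNorm1d(Module):
    """Batch normalisation over (N,) or (N, L) per feature channel.

    Accepts (N, C) or (N, C, L) input.  Training mode normalises with batch
    statistics and updates running estimates; eval mode uses the running
    estimates, making inference deterministic.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features))
        self.running_var = Tensor(np.ones(num_features))
        self.eps = eps
        self.momentum = momentum
        self.frozen = False  # when True, always use running stats

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, view = (0,), (1, -1)
        elif x.ndim == 3:
            axes, view = (0, 2), (1, -1, 1)
        else:
            raise ValueError("BatchNorm1d expects 2-D or 3-D input")
        if self.training and not self.frozen:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu
            self.running_var.data = (1 - m) * self.running_var.data + m * var
            xhat = x.moment_normalize(axes, self.eps)
        else:
            mu = self.running_mean.data.reshape(view)
            sd = np.sqrt(self.running_var.data.reshape(view) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(*view) + self.beta.reshape(*view)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.moment_normalize((-1,), self.eps) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        mask = (u < keep).astype(x.data.dtype)
        mask *= 1.0 / keep
        return x * mask


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``h`` heads over (N, T, d_m)."""

    def __init__(self, d_model: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)
        self.last_attention: np.ndarray | None = None  # (N, h, T, T), diagnostics

    def forward(self, x: Tensor) -> Tensor:
        n, t, dm = x.shape

        def split(z: Tensor) -> Tensor:  # (N,T,dm) -> (N,h,T,d_k)
            return z.reshape(n, t, self.h, self.d_k).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        q, v = q.contiguous(), v.contiguous()
        scores = (q @ k.transpose(0, 1, 3, 2).contiguous()) * (1.0 / math.sqrt(self.d_k))
        att = scores.softmax(axis=-1)
        self.last_attention = att.data
        out = self.drop(att) @ v  # (N,h,T,d_k)
        out = out.transpose(0, 2, 1, 3).reshape(n, t, dm)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-layer-norm encoder block: attention then position-wise MLP."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, dropout, rng)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.ln1(x)))
        return x + self.drop2(self.ff2(self.ff1(self.ln2(x)).relu()))
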
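"""Neural building blocks on top of the autograd engine.

Layers mirror the standard transformer toolkit: :class:`Linear`,
:class:`LayerNorm`, pre-norm :class:`TransformerBlock` with multi-head
self-attention and a GELU MLP. Custom modules are Xavier-uniform
initialised, matching the training recipe used throughout the package.

Every module exposes ``parameters()`` (trainable tensors, depth-first) and
``state_dict()/load_state_dict()`` for checkpointing, and ``flops()``
accounting per layer using the multiply-accumulate = 2 FLOPs convention.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .errors import ConfigurationError

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "xavier_uniform",
]


class Parameter(Tensor):
    """A trainable tensor; ``trainable=False`` freezes it (kept in the state
    dict, excluded from optimisation and parameter counts)."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)
        self.trainable = trainable


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape if shape is not None else (fan_in, fan_out))


class Module:
    """Base class: children discovered by attribute inspection, in definition
    order, which makes parameter traversal (and hence optimisation and
    checkpoints) deterministic."""

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.trainable]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise ConfigurationError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"parameter {name!r}: checkpoint shape {arr.shape} != model shape {p.data.shape}"
                )
            p.data = arr.copy()

    def flops(self) -> dict:
        """Per-layer forward-pass FLOP breakdown for one sample; see metrics."""
        return {}


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.d_in, self.d_out = d_in, d_out
        self.weight = Parameter(xavier_uniform(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ConfigurationError(
                f"Linear expects last dim {self.d_in}, got {x.shape[-1]}"
            )
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def flops(self, n_positions: int = 1) -> dict:
        f = 2 * self.d_in * self.d_out * n_positions
        if self.bias is not None:
            f += self.d_out * n_positions
        return {"linear": f}


class LayerNorm(Module):
    """Layer normalisation over the last axis, eps-stabilised, affine
    initialised to identity (gain 1, bias 0)."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.d = d
        self.eps = eps
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / (var + self.eps).sqrt()
        return y * self.gain + self.bias


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads != 0:
            raise ConfigurationError(f"embed dim {d} not divisible by heads {heads}")
        self.d, self.heads = d, heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., N, d)
        n = x.shape[-2]
        h, dh = self.heads, self.d // self.heads
        qkv = self.qkv(x)  # (..., N, 3d)
        lead = x.shape[:-2]
        qkv = qkv.reshape(*lead, n, 3, h, dh)
        perm = tuple(range(len(lead))) + tuple(len(lead) + i for i in (1, 2, 0, 3))
        qkv = qkv.transpose(perm)  # (..., 3, h, N, dh)
        q = qkv[(..., 0, slice(None), slice(None), slice(None))]
        k = qkv[(..., 1, slice(None), slice(None), slice(None))]
        v = qkv[(..., 2, slice(None), slice(None), slice(None))]
        att = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = att @ v  # (..., h, N, dh)
        perm_back = tuple(range(out.ndim - 3)) + (out.ndim - 2, out.ndim - 3, out.ndim - 1)
        out = out.transpose(perm_back).reshape(*lead, n, self.d)
        return self.proj(out)

    def flops(self, n_positions: int = 1) -> dict:
        f = self.qkv.flops(n_positions)["linear"] + self.proj.flops(n_positions)["linear"]
        # QK^T and att@V: each n^2 * d MACs
        f += 2 * (2 * n_positions * n_positions * self.d)
        return {"self_attention": f}


class TransformerBlock(Module):
    """Pre-norm transformer encoder block: LN → MHSA → residual, LN → MLP
    (GELU, expansion mlp_ratio) → residual."""

    def __init__(self, d: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.norm2 = LayerNorm(d)
        hidden = int(d * mlp_ratio)
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x

    def flops(self, n_positions: int = 1) -> dict:
        f = self.attn.flops(n_positions)["self_attention"]
        f += self.fc1.flops(n_positions)["linear"] + self.fc2.flops(n_positions)["linear"]
        return {"transformer_block": f}
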
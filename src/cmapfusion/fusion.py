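"""Cross-modal attention fusion and the prediction head.

Queries come from the (pruned) image branch, keys and values from the lab
branch: Q = W_Q F_I', K = W_K F_L', V = W_V F_L', and
Attn = softmax(Q K^T / sqrt(d_k)) V. Applied literally to one vector per
branch the softmax is over a single key and collapses to 1, so
Attn = W_V F_L' exactly; this degenerate "vector mode" is the default and
is asserted, not hidden. Token mode (``tokens = m > 1``) reshapes each
projected branch vector into m tokens of dimension d/m and runs standard
scaled dot-product attention across tokens, which makes the attention
weights input-dependent.

The attention output is residual-connected with the image branch and layer
normalised (F_fusion), then a bottleneck + classification head produces
class probabilities: F_refine = ReLU(W_b F_fusion + b_b),
Y_hat = softmax(W_o F_refine + b_o).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .errors import ConfigurationError, ShapeError
from .nn import LayerNorm, Linear, Module, Parameter, xavier_uniform

__all__ = [
    "cross_modal_attention",
    "fuse_residual_norm",
    "predict_head",
    "CrossModalAttention",
    "FusionNorm",
    "PredictHead",
]


# ------------------------------------------------------------ reference ops

def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def cross_modal_attention(
    f_prune_i: np.ndarray,
    f_prune_l: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    tokens: int = 1,
) -> np.ndarray:
    """Reference single-sample attention on length-d branch vectors."""
    f_prune_i = np.asarray(f_prune_i, dtype=np.float64)
    f_prune_l = np.asarray(f_prune_l, dtype=np.float64)
    d = f_prune_i.shape[-1]
    if f_prune_l.shape[-1] != d:
        raise ShapeError("branch features must share length d")
    for name, w in (("W_Q", w_q), ("W_K", w_k), ("W_V", w_v)):
        if np.asarray(w).shape != (d, d):
            raise ConfigurationError(f"{name} must be {d}x{d}")
    if tokens == 1:
        # softmax over a single key is 1: Attn = W_V . F_L' exactly
        return w_v @ f_prune_l
    if d % tokens:
        raise ConfigurationError(f"d={d} not divisible by tokens={tokens}")
    dm = d // tokens
    q = (w_q @ f_prune_i).reshape(tokens, dm)
    k = (w_k @ f_prune_l).reshape(tokens, dm)
    v = (w_v @ f_prune_l).reshape(tokens, dm)
    att = _softmax(q @ k.T / np.sqrt(dm))
    return (att @ v).reshape(d)


def fuse_residual_norm(
    attn: np.ndarray,
    f_prune_i: np.ndarray,
    gain: np.ndarray | None = None,
    bias: np.ndarray | None = None,
    eps: float = 1e-5,
) -> np.ndarray:
    """F_fusion = LayerNorm(Attn + F_I') with affine init (gain 1, bias 0)."""
    attn = np.asarray(attn, dtype=np.float64)
    f_prune_i = np.asarray(f_prune_i, dtype=np.float64)
    if attn.shape != f_prune_i.shape:
        raise ShapeError(f"attention shape {attn.shape} != image branch {f_prune_i.shape}")
    x = attn + f_prune_i
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    y = (x - mu) / np.sqrt(var + eps)
    if gain is not None:
        y = y * gain
    if bias is not None:
        y = y + bias
    return y


def predict_head(
    f_fusion: np.ndarray,
    w_b: np.ndarray,
    b_b: np.ndarray,
    w_o: np.ndarray,
    b_o: np.ndarray,
) -> np.ndarray:
    """F_refine = ReLU(W_b F_fusion + b_b); Y_hat = softmax(W_o F_refine + b_o)."""
    if np.asarray(w_o).shape[0] != np.asarray(w_b).shape[1]:
        raise ConfigurationError("bottleneck and classifier widths disagree")
    if np.asarray(w_o).shape[1] < 2:
        raise ConfigurationError("need at least 2 classes")
    refine = np.maximum(np.asarray(f_fusion) @ np.asarray(w_b) + b_b, 0.0)
    return _softmax(refine @ np.asarray(w_o) + b_o)


# ------------------------------------------------------------------- modules

class CrossModalAttention(Module):
    """Batched differentiable cross-modal attention (B, d) x (B, d) -> (B, d)."""

    def __init__(self, d: int, rng: np.random.Generator, tokens: int = 1):
        if tokens > 1 and d % tokens:
            raise ConfigurationError(f"d={d} not divisible by tokens={tokens}")
        self.d = d
        self.tokens = tokens
        self.w_q = Parameter(xavier_uniform(rng, d, d))
        self.w_k = Parameter(xavier_uniform(rng, d, d))
        self.w_v = Parameter(xavier_uniform(rng, d, d))

    def __call__(self, f_i: Tensor, f_l: Tensor) -> Tensor:
        if self.tokens == 1:
            return f_l @ self.w_v.transpose()
        b = f_i.shape[0]
        m, dm = self.tokens, self.d // self.tokens
        q = (f_i @ self.w_q.transpose()).reshape(b, m, dm)
        k = (f_l @ self.w_k.transpose()).reshape(b, m, dm)
        v = (f_l @ self.w_v.transpose()).reshape(b, m, dm)
        att = ((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dm))).softmax(axis=-1)
        return (att @ v).reshape(b, self.d)

    def flops(self) -> dict:
        if self.tokens == 1:
            return {"cross_attention": 2 * self.d * self.d}
        m, dm = self.tokens, self.d // self.tokens
        proj = 3 * 2 * self.d * self.d
        att = 2 * (2 * m * m * dm)
        return {"cross_attention": proj + att}


class FusionNorm(Module):
    """Residual add + layer norm producing F_fusion."""

    def __init__(self, d: int):
        self.norm = LayerNorm(d)

    def __call__(self, attn: Tensor, f_prune_i: Tensor) -> Tensor:
        return self.norm(attn + f_prune_i)


class PredictHead(Module):
    """Bottleneck (ReLU) + classification (softmax) head."""

    def __init__(self, d: int, n_classes: int, rng: np.random.Generator, bottleneck: int | None = None):
        if n_classes < 2:
            raise ConfigurationError("classification head needs at least 2 classes")
        self.bottleneck_dim = bottleneck if bottleneck is not None else max(4, d // 2)
        self.fc_b = Linear(d, self.bottleneck_dim, rng)
        self.fc_o = Linear(self.bottleneck_dim, n_classes, rng)

    def __call__(self, f_fusion: Tensor) -> tuple[Tensor, Tensor]:
        refine = self.fc_b(f_fusion).relu()
        return refine, self.fc_o(refine).softmax(axis=-1)

    def flops(self) -> dict:
        return {
            "head_bottleneck": self.fc_b.flops()["linear"],
            "head_classifier": self.fc_o.flops()["linear"],
        }
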
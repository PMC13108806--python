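"""Dynamic feature pruning with an adaptive mean + lambda*std threshold.

The concatenated bimodal feature F_cat = [F_I ; F_L] (length 2d) is scored
by a dimension-preserving sigmoid layer, S = sigmoid(W_s F_cat + b_s), and
gated by the per-sample binary mask

    M_j = 1  iff  S_j >= tau,     tau = mean(S) + lambda * std(S),

where std is the population standard deviation over this sample's 2d
scores. lambda (default 0.3) trades pruning rate against feature retention:
larger lambda raises tau and retains fewer dimensions. If the rule would
zero the whole mask (possible when (max-mean)/std < lambda), the single
highest-scoring entry is retained, ties broken toward the lowest index, so
the fusion stage never receives an all-zero input.

Training uses a straight-through estimator: the forward pass applies the
hard mask, the backward pass flows through the relaxation
sigmoid((S - tau)/temperature) (temperature 0.1). The sparsity loss is
computed on the relaxed mask during training and on the hard mask for
reporting.

The pure-numpy functions here are the reference semantics; the
:class:`SmartTrimGate` module wraps them for batched, differentiable use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .errors import ConfigurationError, ShapeError
from .nn import Linear, Module

__all__ = [
    "importance_scores",
    "dynamic_threshold",
    "build_mask",
    "apply_mask",
    "split_branches",
    "PruningState",
    "SmartTrimGate",
]


def importance_scores(f_cat: np.ndarray, w_s: np.ndarray, b_s: np.ndarray) -> np.ndarray:
    """S = sigmoid(W_s . F_cat + b_s); W_s is (2d, 2d), dimension-preserving."""
    f_cat = np.asarray(f_cat, dtype=np.float64)
    w_s = np.asarray(w_s, dtype=np.float64)
    if w_s.shape != (f_cat.shape[-1], f_cat.shape[-1]):
        raise ConfigurationError(
            f"scorer weight shape {w_s.shape} incompatible with feature length {f_cat.shape[-1]}"
        )
    z = f_cat @ w_s.T + b_s
    return 1.0 / (1.0 + np.exp(-z))


def dynamic_threshold(scores: np.ndarray, lam: float) -> float | np.ndarray:
    """tau = mean(S) + lambda * population-std(S), per sample (last axis)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot compute a threshold on an empty score vector")
    return scores.mean(axis=-1) + lam * scores.std(axis=-1)


def build_mask(scores: np.ndarray, tau: float | np.ndarray) -> np.ndarray:
    """M_j = 1 iff S_j >= tau (inclusive); all-zero masks fall back to
    keeping the single largest score (lowest index on ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    tau_arr = np.asarray(tau, dtype=np.float64)[..., None] if np.ndim(tau) else tau
    mask = (scores >= tau_arr).astype(np.float64)
    if mask.ndim == 1:
        if mask.sum() == 0:
            mask[int(np.argmax(scores))] = 1.0
        return mask
    empty = mask.sum(axis=-1) == 0
    if empty.any():
        top = np.argmax(scores[empty], axis=-1)
        mask[np.flatnonzero(empty), top] = 1.0
    return mask


def apply_mask(f_cat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise gating; masked entries are exactly zero."""
    f_cat = np.asarray(f_cat, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if f_cat.shape != mask.shape:
        raise ShapeError(f"feature shape {f_cat.shape} != mask shape {mask.shape}")
    return f_cat * mask


def split_branches(f_prune: np.ndarray, d: int | None = None):
    """Undo the [F_I ; F_L] concatenation: first d entries are the image
    branch, last d the lab branch."""
    f_prune = np.asarray(f_prune)
    total = f_prune.shape[-1]
    if d is None:
        if total % 2:
            raise ShapeError(f"cannot split odd length {total} without an explicit d")
        d = total // 2
    if total != 2 * d:
        raise ShapeError(f"feature length {total} != 2*d with d={d}")
    return f_prune[..., :d], f_prune[..., d:]


@dataclass
class PruningState:
    """All intermediates of one gating pass (per sample or batched)."""

    scores: np.ndarray
    lam: float
    tau: np.ndarray
    mask: np.ndarray
    f_prune: np.ndarray
    f_prune_image: np.ndarray
    f_prune_lab: np.ndarray


class SmartTrimGate(Module):
    """Differentiable gate over batched features (B, 2d).

    ``enabled=False`` turns the gate into the identity (ablation contract):
    scores are still produced for inspection but the mask is all ones.
    """

    def __init__(
        self,
        d: int,
        rng: np.random.Generator,
        lam: float = 0.3,
        temperature: float = 0.1,
        enabled: bool = True,
    ):
        self.d = d
        self.lam = lam
        self.temperature = temperature
        self.enabled = enabled
        self.scorer = Linear(2 * d, 2 * d, rng)

    def __call__(self, f_cat: Tensor):
        """Returns (f_prune, scores, relaxed_mask, state).

        ``f_prune`` carries straight-through gradients; ``state`` holds the
        hard-mask numpy view used for metrics.
        """
        s = self.scorer(f_cat).sigmoid()  # (B, 2d)
        if not self.enabled:
            ones = np.ones_like(s.data)
            state = self._state(s.data, np.full(s.data.shape[0], np.nan), ones, f_cat.data)
            return f_cat, s, Tensor(ones), state

        mu = s.mean(axis=-1, keepdims=True)
        var = ((s - mu) * (s - mu)).mean(axis=-1, keepdims=True)
        tau = mu + self.lam * (var + 1e-12).sqrt()
        relaxed = ((s - tau) * (1.0 / self.temperature)).sigmoid()

        hard = build_mask(s.data, dynamic_threshold(s.data, self.lam))
        # straight-through: forward value = hard, gradient = d(relaxed)/d(...)
        mask_ste = relaxed + Tensor(hard - relaxed.data)
        f_prune = f_cat * mask_ste
        state = self._state(s.data, dynamic_threshold(s.data, self.lam), hard, f_prune.data)
        return f_prune, s, relaxed, state

    def _state(self, scores, tau, mask, f_prune) -> PruningState:
        f_i, f_l = split_branches(f_prune, self.d)
        return PruningState(
            scores=scores,
            lam=self.lam,
            tau=np.asarray(tau),
            mask=mask,
            f_prune=f_prune,
            f_prune_image=f_i,
            f_prune_lab=f_l,
        )

    def flops(self) -> dict:
        return {"smarttrim_scorer": self.scorer.flops()["linear"]}
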
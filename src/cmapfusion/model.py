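"""The full cross-modal alignment-pruning-fusion model.

Composition per forward pass::

    image --(ViT or conv encoder)--> F_I  (d)
    lab   --(per-step MLP + pool)--> F_L  (d)
    F_cat = [F_I ; F_L]              (2d)
    SmartTrim gate  -> F_prune, split into image/lab branches
    cross-modal attention + residual layer norm -> F_fusion   (d)
    bottleneck + softmax head -> class probabilities Y_hat    (C)

Ablation toggles replace modules with documented minimal substitutes:
without the image transformer a small strided conv encoder of matched
output dim; without SmartTrim an identity gate; without the cross-modal
transformer a linear 2d -> d adapter feeding the same head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .config import ModelConfig, FusionConfig, SmartTrimConfig
from .encoders import ConvImageEncoder, LabEncoder, ViTImageEncoder
from .errors import ShapeError
from .fusion import CrossModalAttention, FusionNorm, PredictHead
from .nn import Linear, Module
from .smarttrim import PruningState, SmartTrimGate
from .synthetic import MultimodalSample

__all__ = ["AblationToggle", "FeatureBundle", "FusionOutput", "CMAPFusionModel"]


@dataclass
class AblationToggle:
    use_image_transformer: bool = True
    use_smarttrim: bool = True
    use_cmt: bool = True

    def tag(self) -> str:
        marks = ["vit" if self.use_image_transformer else "-",
                 "smarttrim" if self.use_smarttrim else "-",
                 "cmt" if self.use_cmt else "-"]
        return "+".join(marks)


@dataclass
class FeatureBundle:
    """Aligned modality embeddings and their concatenation (batched)."""

    f_image: np.ndarray  # (B, d)
    f_lab: np.ndarray  # (B, d)
    f_cat: np.ndarray  # (B, 2d)


@dataclass
class FusionOutput:
    attn: np.ndarray  # (B, d)
    f_fusion: np.ndarray  # (B, d)
    f_refine: np.ndarray  # (B, d/2)
    probs: np.ndarray  # (B, C)


class CMAPFusionModel(Module):
    def __init__(
        self,
        cfg: ModelConfig,
        rng: np.random.Generator,
        smarttrim: SmartTrimConfig | None = None,
        fusion: FusionConfig | None = None,
        toggle: AblationToggle | None = None,
    ):
        smarttrim = smarttrim or SmartTrimConfig()
        fusion = fusion or FusionConfig()
        self.toggle = toggle or AblationToggle()
        if not self.toggle.use_smarttrim:
            smarttrim = SmartTrimConfig(lam=smarttrim.lam, temperature=smarttrim.temperature, enabled=False)
        if not self.toggle.use_cmt:
            fusion = FusionConfig(enabled=False, tokens=fusion.tokens, heads=fusion.heads)
        self.cfg = cfg
        self.st_cfg = smarttrim
        self.fu_cfg = fusion

        if self.toggle.use_image_transformer:
            self.image_encoder: Module = ViTImageEncoder(
                cfg.image_size, cfg.patch, cfg.d, cfg.depth, cfg.heads, cfg.mlp_ratio, rng
            )
        else:
            self.image_encoder = ConvImageEncoder(cfg.image_size, cfg.d, rng)
        self.lab_encoder = LabEncoder(cfg.K, cfg.d, rng, hidden=cfg.lab_hidden)

        self.gate = (
            SmartTrimGate(cfg.d, rng, lam=smarttrim.lam, temperature=smarttrim.temperature)
            if smarttrim.enabled
            else None
        )
        if fusion.enabled:
            self.attention = CrossModalAttention(cfg.d, rng, tokens=fusion.tokens)
            self.fuse_norm = FusionNorm(cfg.d)
            self.adapter = None
        else:
            self.attention = None
            self.fuse_norm = None
            self.adapter = Linear(2 * cfg.d, cfg.d, rng)
        self.head = PredictHead(cfg.d, cfg.n_classes, rng, bottleneck=cfg.bottleneck)

    # ------------------------------------------------------------ forward

    def forward(self, images: np.ndarray, labs: np.ndarray) -> dict:
        """Batched differentiable forward pass; returns all intermediates
        (autograd Tensors) keyed by name."""
        if images.ndim != 4:
            raise ShapeError(f"expected batched images (B,H,W,C), got {images.shape}")
        if labs.ndim != 3:
            raise ShapeError(f"expected batched lab series (B,T,K), got {labs.shape}")
        f_i = self.image_encoder(images)  # (B, d)
        f_l = self.lab_encoder(labs)  # (B, d)
        f_cat = concat([f_i, f_l], axis=-1)  # (B, 2d)

        if self.gate is not None:
            f_prune, scores, relaxed, state = self.gate(f_cat)
        else:
            b = f_cat.shape[0]
            ones = np.ones_like(f_cat.data)
            f_prune, relaxed = f_cat, Tensor(ones)
            scores = None
            d = self.cfg.d
            state = PruningState(
                scores=np.full_like(f_cat.data, np.nan),
                lam=self.st_cfg.lam,
                tau=np.full(b, np.nan),
                mask=ones,
                f_prune=f_cat.data,
                f_prune_image=f_cat.data[:, :d],
                f_prune_lab=f_cat.data[:, d:],
            )

        d = self.cfg.d
        if self.attention is not None:
            fp_i, fp_l = f_prune[:, :d], f_prune[:, d:]
            attn = self.attention(fp_i, fp_l)
            f_fusion = self.fuse_norm(attn, fp_i)
        else:
            attn = None
            f_fusion = self.adapter(f_prune)
        refine, probs = self.head(f_fusion)

        return {
            "f_image": f_i,
            "f_lab": f_l,
            "f_cat": f_cat,
            "f_prune": f_prune,
            "scores": scores,
            "relaxed_mask": relaxed,
            "pruning_state": state,
            "attn": attn,
            "f_fusion": f_fusion,
            "f_refine": refine,
            "probs": probs,
        }

    def forward_full(self, samples) -> tuple[FeatureBundle, PruningState, FusionOutput]:
        """Inference-style forward over a sample, list of samples, or
        (images, labs) arrays; returns plain-array result bundles."""
        if isinstance(samples, MultimodalSample):
            samples = [samples]
        if isinstance(samples, tuple) and len(samples) == 2:
            images, labs = samples
        else:
            images = np.stack([s.image for s in samples])
            labs = np.stack([s.lab for s in samples])
        out = self.forward(np.asarray(images, dtype=np.float64), np.asarray(labs, dtype=np.float64))
        bundle = FeatureBundle(
            f_image=out["f_image"].data, f_lab=out["f_lab"].data, f_cat=out["f_cat"].data
        )
        fusion = FusionOutput(
            attn=out["attn"].data if out["attn"] is not None else np.zeros_like(out["f_fusion"].data),
            f_fusion=out["f_fusion"].data,
            f_refine=out["f_refine"].data,
            probs=out["probs"].data,
        )
        return bundle, out["pruning_state"], fusion

    # --------------------------------------------------------- accounting

    def flops(self) -> dict:
        """Forward-pass FLOPs for one sample (MAC = 2 FLOPs), per layer."""
        out = dict(self.image_encoder.flops())
        lab = self.lab_encoder.flops(self.cfg.T)
        out.update(lab)
        if self.gate is not None:
            out.update(self.gate.flops())
        if self.attention is not None:
            out.update(self.attention.flops())
        else:
            out["fusion_adapter"] = self.adapter.flops()["linear"]
        out.update(self.head.flops())
        return out
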
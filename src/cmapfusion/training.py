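"""Training loop, evaluation, and checkpointing.

Optimisation follows the framework's recipe: AdamW (beta1=0.9, beta2=0.999,
decoupled weight decay 1e-5), batch size 32, learning rate warming up
linearly over the first epochs to the initial rate 1e-4 and then cosine-
annealed to the final rate 1e-6 at the last epoch, early stopping on
validation macro-F1 with patience 10 (best weights restored). Custom
modules are Xavier-uniform initialised at construction.

All randomness (weight init, shuffling) derives from the run seed; a fixed
seed reproduces histories and reports bit-identically on one machine.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, TrainConfig
from .errors import CmapFusionError
from .metrics import (
    MetricReport,
    auc_from_scores,
    confusion_matrix,
    count_parameters,
    cross_modal_similarity,
    estimate_flops,
    feature_sparsity,
    kappa_from_confusion,
    loss_total,
    loss_total_tensor,
    macro_f1,
)
from .model import AblationToggle, CMAPFusionModel
from .preprocessing import LabStats, fit_lab_stats, preprocess_image, preprocess_lab
from .synthetic import MultimodalSample

__all__ = [
    "AdamW",
    "lr_schedule",
    "prepare_arrays",
    "TrainResult",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


class AdamW(object):
    """Adam with decoupled weight decay over a parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, weight_decay=1e-5, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Linear warmup to ``lr_init`` over the warmup epochs, then cosine
    annealing reaching ``lr_final`` exactly at the last epoch."""
    if epoch < cfg.warmup_epochs:
        return cfg.lr_init * (epoch + 1) / cfg.warmup_epochs
    last = cfg.max_epochs - 1
    if last <= cfg.warmup_epochs:
        return cfg.lr_init
    frac = (epoch - cfg.warmup_epochs) / (last - cfg.warmup_epochs)
    return cfg.lr_final + 0.5 * (cfg.lr_init - cfg.lr_final) * (1 + np.cos(np.pi * min(frac, 1.0)))


def prepare_arrays(
    samples: list[MultimodalSample],
    target_size: tuple,
    t_target: int,
    stats: LabStats,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess a sample list into (images, labs, labels) arrays."""
    images = np.stack(
        [preprocess_image(s.image, target_size=target_size, train_mode=train_mode, rng=rng) for s in samples]
    )
    labs = np.stack([preprocess_lab(s.lab, stats, t_target=t_target) for s in samples])
    labels = np.array([s.label for s in samples], dtype=int)
    return images, labs, labels


@dataclass
class TrainResult:
    model: CMAPFusionModel
    stats: LabStats
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0


def _batch_cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity for (B, d) arrays."""
    num = np.einsum("bd,bd->b", a, b)
    den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    return num / den


def _forward_batches(model, images, labs, batch_size):
    """Inference forward in batches; concatenated plain-array outputs."""
    outs = {"probs": [], "f_image": [], "f_lab": [], "f_prune": [], "mask": [], "scores": []}
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        out = model.forward(images[sl], labs[sl])
        outs["probs"].append(out["probs"].data)
        outs["f_image"].append(out["f_image"].data)
        outs["f_lab"].append(out["f_lab"].data)
        outs["f_prune"].append(out["pruning_state"].f_prune)
        outs["mask"].append(out["pruning_state"].mask)
        outs["scores"].append(out["pruning_state"].scores)
    return {k: np.concatenate(v) for k, v in outs.items()}


def evaluate(
    model: CMAPFusionModel,
    samples: list[MultimodalSample],
    stats: LabStats,
    alpha: float = 0.1,
    beta: float = 0.05,
    batch_size: int = 64,
) -> MetricReport:
    """Run the metric suite over a split. Deterministic given weights."""
    if len(samples) == 0:
        raise ValueError("cannot evaluate an empty split")
    h, w, _ = model.cfg.image_size
    images, labs, labels = prepare_arrays(samples, (h, w), model.cfg.T, stats)
    out = _forward_batches(model, images, labs, batch_size)
    preds = np.argmax(out["probs"], axis=1)
    cm = confusion_matrix(labels, preds, model.cfg.n_classes)
    loss = loss_total(out["probs"], labels, out["f_image"], out["f_lab"], out["mask"], alpha, beta)
    sims = _batch_cosine(out["f_image"], out["f_lab"])
    n_flops, _ = estimate_flops(model)
    return MetricReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        f1_macro=macro_f1(cm),
        auc_macro=auc_from_scores(out["probs"], labels),
        kappa=kappa_from_confusion(cm),
        feature_sparsity_pct=feature_sparsity(out["f_prune"]),
        cross_modal_sim=float(np.mean(sims)),
        n_params=count_parameters(model),
        flops=n_flops,
        loss=loss,
        confusion=cm,
    )


def train(
    train_samples: list[MultimodalSample],
    val_samples: list[MultimodalSample],
    config: RunConfig,
    toggle: AblationToggle | None = None,
    seed: int | None = None,
) -> TrainResult:
    """Train a model on preprocessed splits with the standard recipe.

    ``seed`` (default ``config.train.seed``) drives weight initialisation
    and shuffling; per-epoch shuffle generators are derived from
    ``(seed, epoch)`` so ablation variants sharing a seed see identical
    data order.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    tc = config.train
    seed = tc.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = CMAPFusionModel(config.model, rng, config.smarttrim, config.fusion, toggle)

    stats = fit_lab_stats([s.lab for s in train_samples])
    h, w, _ = config.model.image_size
    aug_rng = np.random.default_rng([seed, 7919]) if tc.augment else None
    tr_images, tr_labs, tr_labels = prepare_arrays(
        train_samples, (h, w), config.model.T, stats, train_mode=tc.augment, rng=aug_rng
    )

    opt = AdamW(
        model.trainable_parameters(),
        lr=tc.lr_init,
        beta1=tc.beta1,
        beta2=tc.beta2,
        weight_decay=tc.weight_decay,
    )

    va_images, va_labs, va_labels = prepare_arrays(val_samples, (h, w), config.model.T, stats)

    result = TrainResult(model=model, stats=stats)
    best_state = model.state_dict()
    epochs_since_best = 0
    n = len(train_samples)
    for epoch in range(tc.max_epochs):
        opt.lr = lr_schedule(epoch, tc)
        order = np.random.default_rng([seed, epoch]).permutation(n)
        epoch_losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            out = model.forward(tr_images[idx], tr_labs[idx])
            loss, breakdown = loss_total_tensor(
                out["probs"], tr_labels[idx], out["f_image"], out["f_lab"],
                out["relaxed_mask"], tc.alpha, tc.beta,
            )
            if not np.isfinite(loss.data):
                raise CmapFusionError(
                    f"training diverged at epoch {epoch}: loss={float(loss.data)!r} "
                    f"(components cls={breakdown.cls!r} cm={breakdown.cm!r} sparse={breakdown.sparse!r})"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(breakdown)

        out = _forward_batches(model, va_images, va_labs, 128)
        preds = np.argmax(out["probs"], axis=1)
        cm = confusion_matrix(va_labels, preds, config.model.n_classes)
        val_f1 = macro_f1(cm)
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss_cls": float(np.mean([b.cls for b in epoch_losses])),
            "train_loss_cm": float(np.mean([b.cm for b in epoch_losses])),
            "train_loss_sparse": float(np.mean([b.sparse for b in epoch_losses])),
            "train_loss_total": float(np.mean([b.total for b in epoch_losses])),
            "val_accuracy": float(np.trace(cm) / cm.sum()),
            "val_f1_macro": val_f1,
            "val_sparsity_pct": feature_sparsity(out["f_prune"]),
            "val_cross_modal_sim": float(np.mean(_batch_cosine(out["f_image"], out["f_lab"]))),
        }
        result.history.append(record)
        if val_f1 >= result.best_val_f1:
            # ties keep the later state (more-trained model at equal
            # validation F1); patience counts from the last strict gain
            if val_f1 > result.best_val_f1:
                epochs_since_best = 0
            else:
                epochs_since_best += 1
            result.best_val_f1 = val_f1
            result.best_epoch = epoch
            best_state = model.state_dict()
        else:
            epochs_since_best += 1
        if epochs_since_best >= tc.patience:
            break
    model.load_state_dict(best_state)
    return result


# ---------------------------------------------------------------- checkpoint

def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(result: TrainResult, config: RunConfig, path: str) -> None:
    """Single-file weight map + lab stats + config hash (npz)."""
    state = result.model.state_dict()
    toggle = result.model.toggle
    meta = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "toggle": [toggle.use_image_transformer, toggle.use_smarttrim, toggle.use_cmt],
        "best_epoch": result.best_epoch,
        "best_val_f1": result.best_val_f1,
    }
    arrays = {f"param::{k}": v for k, v in state.items()}
    arrays.update(
        {f"stats::{k}": getattr(result.stats, k) for k in ("mean", "sd", "median", "vmin", "vmax")}
    )
    np.savez(path, meta=json.dumps(meta, sort_keys=True, default=str), **arrays)


def load_checkpoint(path: str, config: RunConfig) -> TrainResult:
    """Rebuild a model + lab stats from a checkpoint; the stored config hash
    must match the supplied config."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["config_hash"] != _config_hash(config):
            raise CmapFusionError(
                "checkpoint was written with a different configuration "
                f"({meta['config_hash']} != {_config_hash(config)})"
            )
        toggle = AblationToggle(*[bool(x) for x in meta["toggle"]])
        rng = np.random.default_rng(0)
        model = CMAPFusionModel(config.model, rng, config.smarttrim, config.fusion, toggle)
        model.load_state_dict(
            {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("param::")}
        )
        stats = LabStats(
            **{k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("stats::")}
        )
    result = TrainResult(model=model, stats=stats)
    result.best_epoch = int(meta["best_epoch"])
    result.best_val_f1 = float(meta["best_val_f1"])
    return result
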
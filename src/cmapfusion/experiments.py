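"""Experiment protocols: module ablation, lambda sensitivity, perturbation
robustness, and repeated stratified cross-validation.

Every protocol derives all randomness from explicit seeds and shares data
splits across its variants (ablation rows with the same seed see the same
split and batch order), so differences between rows reflect the toggled
modules or parameters, not sampling noise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig
from .errors import ConfigurationError
from .metrics import MetricReport
from .model import AblationToggle, CMAPFusionModel
from .preprocessing import perturb_image_noise, perturb_lab_missing, stratified_indices, stratified_split
from .synthetic import SyntheticDataset
from .training import TrainResult, evaluate, prepare_arrays, train

__all__ = [
    "ABLATION_ROWS",
    "AblationRow",
    "run_ablation",
    "sweep_lambda",
    "run_robustness",
    "cross_validate",
    "lab_dim_importance",
]

# the seven toggle combinations of the ablation protocol, in table order:
# full; -ViT; -SmartTrim; -CMT; -ViT-SmartTrim; -ViT-CMT; -SmartTrim-CMT
ABLATION_ROWS: tuple[AblationToggle, ...] = (
    AblationToggle(True, True, True),
    AblationToggle(False, True, True),
    AblationToggle(True, False, True),
    AblationToggle(True, True, False),
    AblationToggle(False, False, True),
    AblationToggle(False, True, False),
    AblationToggle(True, False, False),
)

_MEAN_KEYS = (
    "accuracy",
    "f1_macro",
    "auc_macro",
    "kappa",
    "feature_sparsity_pct",
    "cross_modal_sim",
)


def _mean_report(reports: list[MetricReport]) -> dict:
    out = {k: float(np.mean([getattr(r, k) for r in reports])) for k in _MEAN_KEYS}
    out["n_params"] = int(reports[0].n_params)
    out["flops"] = int(reports[0].flops)
    return out


@dataclass
class AblationRow:
    toggle: AblationToggle
    reports: list[MetricReport] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        return _mean_report(self.reports)

    def to_dict(self) -> dict:
        return {
            "use_image_transformer": self.toggle.use_image_transformer,
            "use_smarttrim": self.toggle.use_smarttrim,
            "use_cmt": self.toggle.use_cmt,
            "tag": self.toggle.tag(),
            "per_seed": [r.to_dict() for r in self.reports],
            "mean": self.mean,
        }


def _train_eval_once(dataset: SyntheticDataset, config: RunConfig, toggle, seed: int):
    tr, va, te = stratified_split(dataset, seed=seed)
    result = train(tr, va, config, toggle=toggle, seed=seed)
    report = evaluate(result.model, te, result.stats, config.train.alpha, config.train.beta)
    return result, report


def run_ablation(dataset: SyntheticDataset, config: RunConfig, seeds=(0, 1, 2)) -> list[AblationRow]:
    """Train/evaluate the seven module combinations with shared seeds.

    For each seed, every row uses the same stratified split and the same
    batch order; the test-set metric suite is reported per row.
    """
    rows = [AblationRow(toggle=t) for t in ABLATION_ROWS]
    for seed in seeds:
        for row in rows:
            _, report = _train_eval_once(dataset, config, row.toggle, seed)
            row.reports.append(report)
    return rows


def sweep_lambda(
    dataset: SyntheticDataset,
    config: RunConfig,
    values=(0.1, 0.2, 0.3, 0.4, 0.5),
    seeds=(0, 1, 2),
) -> list[dict]:
    """Train/evaluate the full model at each pruning coefficient lambda,
    sharing seeds (and therefore splits and batch order) across values."""
    rows = []
    for lam in values:
        cfg = copy.deepcopy(config)
        cfg.smarttrim.lam = float(lam)
        reports = [_train_eval_once(dataset, cfg, None, seed)[1] for seed in seeds]
        row = {"lambda": float(lam), "per_seed": [r.to_dict() for r in reports], "mean": _mean_report(reports)}
        rows.append(row)
    return rows


def run_robustness(
    dataset_or_split,
    result: TrainResult,
    levels=(0.0, 0.1, 0.2, 0.3, 0.4),
    perturb_seeds=(0, 1, 2),
    v_max: float = 1.0,
) -> dict:
    """Accuracy-vs-intensity curves for image Gaussian noise and lab masking.

    Perturbations act on the preprocessed inputs (standardised images,
    [0,1]-scaled series); level 0 reproduces the unperturbed evaluation
    exactly. Each nonzero level is averaged over ``perturb_seeds``.
    """
    samples = list(dataset_or_split)
    model, stats = result.model, result.stats
    h, w, _ = model.cfg.image_size
    images, labs, labels = prepare_arrays(samples, (h, w), model.cfg.T, stats)

    def _accuracy(imgs, lbs):
        preds = []
        for start in range(0, len(imgs), 64):
            sl = slice(start, start + 64)
            out = model.forward(imgs[sl], lbs[sl])
            preds.append(np.argmax(out["probs"].data, axis=1))
        return float(np.mean(np.concatenate(preds) == labels))

    base = _accuracy(images, labs)
    curves = {"levels": [float(l) for l in levels], "image_noise": [], "lab_missing": [], "baseline": base}
    for level in levels:
        if level == 0:
            curves["image_noise"].append(base)
            curves["lab_missing"].append(base)
            continue
        accs_img, accs_lab = [], []
        for ps in perturb_seeds:
            rng = np.random.default_rng([ps, int(round(level * 1000))])
            noisy = np.stack([perturb_image_noise(im, level, rng, v_max=v_max) for im in images])
            accs_img.append(_accuracy(noisy, labs))
            rng = np.random.default_rng([ps, 1 + int(round(level * 1000))])
            masked = np.stack([perturb_lab_missing(lb, level, stats, rng) for lb in labs])
            accs_lab.append(_accuracy(images, masked))
        curves["image_noise"].append(float(np.mean(accs_img)))
        curves["lab_missing"].append(float(np.mean(accs_lab)))
    return curves


def cross_validate(dataset: SyntheticDataset, config: RunConfig, k: int = 5, n_repeats: int = 3) -> dict:
    """``n_repeats`` independent stratified shuffles, each with k-fold CV;
    per-fold refit, early stopping on a stratified 15% validation carve-out
    of the training folds. Reports per-metric mean and sd over all fits."""
    labels = dataset.labels
    counts = np.bincount(labels)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} samples; min count is {counts.min()}")
    fold_reports: list[MetricReport] = []
    fold_index = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=1000 * config.train.seed + rep)
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            tr_labels = labels[train_idx]
            sub_tr, sub_va = stratified_indices(tr_labels, ratios=(0.85, 0.15), seed=rep * k + fold)
            tr = [dataset[i] for i in train_idx[sub_tr]]
            va = [dataset[i] for i in train_idx[sub_va]]
            te = [dataset[i] for i in test_idx]
            result = train(tr, va, config, seed=config.train.seed + rep)
            fold_reports.append(evaluate(result.model, te, result.stats, config.train.alpha, config.train.beta))
            fold_index.append({"repeat": rep, "fold": fold, "n_test": len(te)})
    summary = {
        k_: {
            "mean": float(np.mean([getattr(r, k_) for r in fold_reports])),
            "sd": float(np.std([getattr(r, k_) for r in fold_reports])),
        }
        for k_ in _MEAN_KEYS
    }
    return {"k": k, "n_repeats": n_repeats, "folds": fold_index, "summary": summary,
            "per_fold": [r.to_dict() for r in fold_reports]}


def lab_dim_importance(result: TrainResult, samples, batch_size: int = 64) -> np.ndarray:
    """Occlusion attribution of the trained pruning scorer to raw lab dims.

    For each raw lab dimension k, replace it (post-preprocessing) with its
    scaled training median and measure the mean absolute change of the
    lab-branch importance-score vector; informative dimensions should move
    the scorer more than pure-noise ones.
    """
    model, stats = result.model, result.stats
    if model.gate is None:
        raise ConfigurationError("lab_dim_importance requires the pruning gate to be enabled")
    h, w, _ = model.cfg.image_size
    images, labs, _ = prepare_arrays(list(samples), (h, w), model.cfg.T, stats)
    d = model.cfg.d

    def _lab_scores(lbs):
        chunks = []
        for start in range(0, len(images), batch_size):
            sl = slice(start, start + batch_size)
            out = model.forward(images[sl], lbs[sl])
            chunks.append(out["pruning_state"].scores[:, d:])
        return np.concatenate(chunks)

    base = _lab_scores(labs)
    med = stats.scaled_median
    importances = np.empty(model.cfg.K)
    for kdim in range(model.cfg.K):
        occluded = labs.copy()
        occluded[:, :, kdim] = med[kdim]
        importances[kdim] = float(np.mean(np.abs(_lab_scores(occluded) - base)))
    return importances
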
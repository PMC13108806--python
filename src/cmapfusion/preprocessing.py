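"""Preprocessing, perturbation, and splitting of paired multimodal data.

Images: resize to the model's input size, optional training-time
augmentation (horizontal flip p=0.5, random crop with area ratio in
[0.8, 1.0] then resize back, 3x3 Gaussian blur with sd in [0, 0.1], applied
in that order), then per-image per-channel z-scoring. A zero-variance
channel standardises to all zeros rather than raising.

Laboratory series: statistics are computed on the *training split only* and
frozen (no leakage into validation/test). The pipeline per sample is
(1) values outside mean +/- 3 sd marked missing, (2) missing values imputed
with the training median, (3) min-max scaled to [0, 1] with training
min/max (constant features map to 0.5), (4) linearly interpolated along
time to the target length, clipped to [0, 1].

Perturbations for robustness testing: additive Gaussian image noise with
variance = intensity * v_max, and random masking of lab entries re-imputed
with the (scaled) training median.

Splitting: stratified train/val/test with largest-remainder rounding so
per-class proportions match the requested ratios as closely as integer
counts allow, and global split sizes are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ShapeError
from .synthetic import SyntheticDataset

__all__ = [
    "preprocess_image",
    "LabStats",
    "fit_lab_stats",
    "preprocess_lab",
    "perturb_image_noise",
    "perturb_lab_missing",
    "stratified_indices",
    "stratified_split",
]


def _resize(image: np.ndarray, hw: tuple) -> np.ndarray:
    if image.shape[:2] == tuple(hw):
        return image.astype(np.float64, copy=True)
    return _sk_resize(image, (*hw, image.shape[2]), preserve_range=True, anti_aliasing=True)


def _zscore(image: np.ndarray) -> np.ndarray:
    mu = image.mean(axis=(0, 1), keepdims=True)
    sd = image.std(axis=(0, 1), keepdims=True)
    out = np.zeros_like(image, dtype=np.float64)
    np.divide(image - mu, sd, out=out, where=sd > 0)
    return out


def preprocess_image(
    image: np.ndarray,
    target_size: tuple = (32, 32),
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resize -> (augment) -> per-image, per-channel z-score."""
    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ShapeError("image must have positive spatial extent")
    th, tw = target_size
    img = _resize(np.asarray(image, dtype=np.float64), (th, tw))
    if train_mode:
        if rng is None:
            raise ValueError("train_mode augmentation requires an rng")
        if rng.random() < 0.5:
            img = img[:, ::-1, :]
        area = rng.uniform(0.8, 1.0)
        side = np.sqrt(area)
        ch, cw = max(1, round(th * side)), max(1, round(tw * side))
        top = int(rng.integers(0, th - ch + 1))
        left = int(rng.integers(0, tw - cw + 1))
        img = _resize(img[top : top + ch, left : left + cw, :], (th, tw))
        sd = rng.uniform(0.0, 0.1)
        if sd > 0:
            img = ndimage.gaussian_filter(img, sigma=(sd, sd, 0), radius=(1, 1, 0))
    return _zscore(img)


@dataclass
class LabStats:
    """Per-feature statistics frozen on the training split."""

    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray

    @property
    def scaled_median(self) -> np.ndarray:
        """Training median mapped through the min-max codec (0.5 when the
        feature is constant)."""
        rng_ = self.vmax - self.vmin
        out = np.full_like(self.median, 0.5)
        np.divide(self.median - self.vmin, rng_, out=out, where=rng_ > 0)
        return np.clip(out, 0.0, 1.0)


def fit_lab_stats(train_series: list[np.ndarray] | np.ndarray) -> LabStats:
    """Fit per-feature stats from training-split series (each T x K).

    Mean/sd are over all raw training values; median/min/max are computed
    after masking 3-sigma outliers, matching the preprocessing pipeline.
    """
    stack = np.concatenate([np.asarray(s, dtype=np.float64) for s in train_series], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    masked = stack.copy()
    masked[np.abs(stack - mean) > 3 * sd] = np.nan
    median = np.nanmedian(masked, axis=0)
    vmin = np.nanmin(masked, axis=0)
    vmax = np.nanmax(masked, axis=0)
    return LabStats(mean=mean, sd=sd, median=median, vmin=vmin, vmax=vmax)


def preprocess_lab(series: np.ndarray, stats: LabStats, t_target: int | None = None) -> np.ndarray:
    """Outlier-mask -> impute -> min-max scale -> interpolate to ``t_target``."""
    x = np.asarray(series, dtype=np.float64).copy()
    if x.ndim != 2:
        raise ShapeError(f"lab series must be T x K, got shape {x.shape}")
    t, k = x.shape
    if t < 2:
        raise ShapeError("lab series needs at least 2 time points")
    # (1) 3-sigma outliers (training stats) -> missing
    x[np.abs(x - stats.mean) > 3 * stats.sd] = np.nan
    # (2) impute with the training median
    nan_mask = np.isnan(x)
    x[nan_mask] = np.broadcast_to(stats.median, x.shape)[nan_mask]
    # (3) min-max scale to [0, 1]; constant feature -> 0.5
    rng_ = stats.vmax - stats.vmin
    scaled = np.full_like(x, 0.5)
    np.divide(x - stats.vmin, rng_, out=scaled, where=rng_ > 0)
    scaled = np.clip(scaled, 0.0, 1.0)
    # (4) linear interpolation along time to t_target
    if t_target is None or t_target == t:
        return scaled
    src = np.linspace(0.0, 1.0, t)
    dst = np.linspace(0.0, 1.0, t_target)
    out = np.empty((t_target, k))
    for j in range(k):
        out[:, j] = np.interp(dst, src, scaled[:, j])
    return out


def perturb_image_noise(
    image: np.ndarray, intensity: float, rng: np.random.Generator, v_max: float = 1.0
) -> np.ndarray:
    """Additive Gaussian noise with variance ``intensity * v_max``; identity
    at intensity 0."""
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity must lie in [0, 1], got {intensity}")
    if intensity == 0:
        return np.array(image, dtype=np.float64, copy=True)
    noise = rng.normal(0.0, np.sqrt(intensity * v_max), size=image.shape)
    return np.asarray(image, dtype=np.float64) + noise


def perturb_lab_missing(
    series: np.ndarray, fraction: float, stats: LabStats, rng: np.random.Generator
) -> np.ndarray:
    """Mask exactly ``round(fraction * T * K)`` uniformly chosen entries and
    re-impute them with the training median.

    Operates on preprocessed ([0, 1]-scaled) series, so the imputation value
    is the median mapped through the same min-max codec.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    x = np.array(series, dtype=np.float64, copy=True)
    t, k = x.shape
    n_mask = int(round(fraction * t * k))
    if n_mask == 0:
        return x
    flat_idx = rng.choice(t * k, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat_idx, (t, k))
    x[rows, cols] = stats.scaled_median[cols]
    return x


def stratified_indices(labels, ratios=(0.7, 0.2, 0.1), seed: int = 0) -> tuple:
    """Deterministic stratified partition of ``range(len(labels))``.

    Global split sizes follow largest-remainder rounding of
    ``len(labels) * ratios``; per-class allocations start from floors and
    leftovers are assigned to the (class, split) cells with the largest
    fractional remainder, subject to the global totals.
    """
    labels = np.asarray(labels, dtype=int)
    ratios = np.asarray(ratios, dtype=float)
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios.sum()!r}")
    n, n_splits = len(labels), len(ratios)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise ValueError("stratified split requires >= 3 samples per class")

    # global split sizes by largest remainder
    ideal = n * ratios
    sizes = np.floor(ideal).astype(int)
    for s in np.argsort(-(ideal - sizes), kind="stable")[: n - sizes.sum()]:
        sizes[s] += 1

    # per-class floors, then leftover cells by fractional remainder
    alloc = {}
    cells = []
    for ci, cls in enumerate(classes):
        ideal_c = counts[ci] * ratios
        floors = np.floor(ideal_c).astype(int)
        alloc[cls] = floors
        for s in range(n_splits):
            cells.append((ideal_c[s] - floors[s], ci, s))
    leftover_per_class = {cls: counts[ci] - alloc[cls].sum() for ci, cls in enumerate(classes)}
    room = sizes - np.sum([alloc[c] for c in classes], axis=0)
    cells.sort(key=lambda t: (-t[0], t[2], t[1]))
    for _ in range(2):  # second pass ignores remainder ordering constraints
        for _, ci, s in cells:
            cls = classes[ci]
            if leftover_per_class[cls] > 0 and room[s] > 0:
                alloc[cls][s] += 1
                leftover_per_class[cls] -= 1
                room[s] -= 1

    rng = np.random.default_rng(seed)
    parts = [[] for _ in range(n_splits)]
    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        start = 0
        for s in range(n_splits):
            take = alloc[cls][s]
            parts[s].extend(idx[start : start + take])
            start += take
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def stratified_split(dataset: SyntheticDataset, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Split a dataset into (train, val, test) lists of samples."""
    idx = stratified_indices([s.label for s in dataset], ratios=ratios, seed=seed)
    return tuple([dataset[i] for i in part] for part in idx)
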
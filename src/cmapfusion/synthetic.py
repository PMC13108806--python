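"""Synthetic paired image + laboratory time-series datasets.

Real cross-modal clinical corpora pair an image per patient with a short
multivariate laboratory series (blood counts, inflammatory markers, ...) and
a diagnosis label. This module generates datasets with the same structure
and a *planted, controllable* class signal so that every downstream module
— encoders, pruning gate, fusion, training loop — can be exercised and
verified without any external download:

* each class c gets a distinct **image motif**: a Gaussian intensity blob at
  a class-specific location (amplitude = ``signal_strength``) over unit
  pixel noise;
* each class gets a distinct **lab temporal template** on the informative
  feature dimensions, again with amplitude ``signal_strength`` over unit
  noise;
* a per-sample scalar latent is injected into *both* modalities with weight
  ``cross_modal_coupling``, giving the encoders a genuinely shared signal to
  align;
* exactly ``round(redundant_fraction * K)`` lab dimensions (the trailing
  ones) are pure N(0,1) noise — the redundancy the pruning gate exists to
  remove.

The on-disk layout is ``images/<sample_id>.png`` + ``labs.csv``
(``sample_id,time_index,f1..fK``) + ``labels.csv`` (``sample_id,label``);
``write_dataset``/``load_dataset`` round-trip it (PNG quantisation is the
only loss, with the affine codec stored in ``meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import SynthSpec
from .errors import InvalidSpecError

__all__ = ["MultimodalSample", "SyntheticDataset", "generate_dataset", "write_dataset", "load_dataset"]


@dataclass
class MultimodalSample:
    """One paired observation: image array, lab series matrix, class label."""

    sample_id: str
    image: np.ndarray  # H x W x C, float
    lab: np.ndarray  # T x K, float
    label: int


@dataclass
class SyntheticDataset:
    """List-like container of samples plus generation metadata."""

    samples: list
    spec: SynthSpec
    informative_dims: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    redundant_dims: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]

    def __iter__(self):
        return iter(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)


def _class_image_motifs(spec: SynthSpec) -> np.ndarray:
    """One additive motif image per class: a Gaussian blob on a ring of
    class-specific angles (for 4 classes these are the quadrant centres)."""
    h, w, c = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    motifs = np.zeros((spec.n_classes, h, w, c))
    radius = min(h, w) / 4.0
    sigma = min(h, w) / 8.0
    for cls in range(spec.n_classes):
        angle = 2 * np.pi * cls / spec.n_classes + np.pi / 4
        cy = h / 2 + radius * np.sin(angle)
        cx = w / 2 + radius * np.cos(angle)
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        motifs[cls] = spec.signal_strength * blob[:, :, None]
    return motifs


def _class_lab_templates(spec: SynthSpec, rng: np.random.Generator, informative: np.ndarray) -> np.ndarray:
    """Class-specific profiles on the informative lab dims: a class-specific
    level offset (the dominant mode of between-disease laboratory
    differences — e.g. elevated inflammatory markers) plus a smooth
    class-specific temporal shape, together unit-RMS then scaled by
    signal_strength; zero on redundant dims."""
    t = np.linspace(0.0, 1.0, spec.T)
    templates = np.zeros((spec.n_classes, spec.T, spec.K))
    for cls in range(spec.n_classes):
        for k in informative:
            offset = rng.normal()
            coef = rng.normal(size=3)
            curve = (
                coef[0] * np.sin(2 * np.pi * t + cls)
                + coef[1] * np.cos(2 * np.pi * t * 2 + k)
                + coef[2] * (t - 0.5)
            )
            profile = offset + curve
            rms = np.sqrt(np.mean(profile**2))
            if rms > 0:
                profile = profile / rms
            templates[cls, :, k] = spec.signal_strength * profile
    return templates


def generate_dataset(spec: SynthSpec) -> SyntheticDataset:
    """Generate a paired dataset per ``spec``. Deterministic in ``spec.seed``.

    Class counts are balanced up to rounding; sample order is a seeded
    shuffle so splits see mixed classes.
    """
    if spec.n_samples <= 0 or spec.n_classes <= 0:
        raise InvalidSpecError("n_samples and n_classes must be positive")
    rng = np.random.default_rng(spec.seed)
    n, c_cls = spec.n_samples, spec.n_classes
    n_red = spec.n_redundant
    informative = np.arange(spec.K - n_red)
    redundant = np.arange(spec.K - n_red, spec.K)

    # balanced labels, then a deterministic shuffle
    labels = np.array([i % c_cls for i in range(n)])
    rng.shuffle(labels)

    motifs = _class_image_motifs(spec)
    templates = _class_lab_templates(spec, rng, informative)

    # fixed unit-RMS loading patterns for the shared latent
    h, w, ch = spec.image_size
    img_load = rng.normal(size=(h, w, ch))
    img_load /= np.sqrt(np.mean(img_load**2))
    lab_load = np.zeros(spec.K)
    if len(informative):
        lab_load[informative] = rng.normal(size=len(informative))
        rms = np.sqrt(np.mean(lab_load[informative] ** 2))
        if rms > 0:
            lab_load[informative] /= rms

    samples = []
    width = len(str(n - 1))
    for i in range(n):
        z = rng.normal()  # shared per-sample latent
        img = rng.normal(size=(h, w, ch)) + motifs[labels[i]]
        img += spec.cross_modal_coupling * z * img_load
        lab = rng.normal(size=(spec.T, spec.K)) + templates[labels[i]]
        lab += spec.cross_modal_coupling * z * lab_load[None, :]
        samples.append(
            MultimodalSample(sample_id=f"s{i:0{width}d}", image=img, lab=lab, label=int(labels[i]))
        )
    return SyntheticDataset(samples=samples, spec=spec, informative_dims=informative, redundant_dims=redundant)


# --------------------------------------------------------------------- disk IO

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the ``images/ + labs.csv + labels.csv`` layout.

    Float images are quantised to 8-bit PNG with a dataset-global affine
    codec recorded in ``meta.json``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    vmin = min(float(s.image.min()) for s in dataset)
    vmax = max(float(s.image.max()) for s in dataset)
    scale = 255.0 / (vmax - vmin) if vmax > vmin else 1.0
    for s in dataset:
        q = np.clip(np.round((s.image - vmin) * scale), 0, 255).astype(np.uint8)
        Image.fromarray(q).save(out / "images" / f"{s.sample_id}.png")

    k = dataset.spec.K
    rows = []
    for s in dataset:
        for t in range(s.lab.shape[0]):
            rows.append([s.sample_id, t, *s.lab[t]])
    labs = pd.DataFrame(rows, columns=["sample_id", "time_index", *[f"f{j+1}" for j in range(k)]])
    labs.to_csv(out / "labs.csv", index=False)
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in dataset], "label": [s.label for s in dataset]}
    ).to_csv(out / "labels.csv", index=False)
    meta = {
        "vmin": vmin,
        "vmax": vmax,
        "spec": {
            "n_samples": dataset.spec.n_samples,
            "n_classes": dataset.spec.n_classes,
            "image_size": list(dataset.spec.image_size),
            "T": dataset.spec.T,
            "K": dataset.spec.K,
            "signal_strength": dataset.spec.signal_strength,
            "cross_modal_coupling": dataset.spec.cross_modal_coupling,
            "redundant_fraction": dataset.spec.redundant_fraction,
            "seed": dataset.spec.seed,
        },
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return out


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read the on-disk layout back into a :class:`SyntheticDataset`."""
    src = Path(in_dir)
    with open(src / "meta.json") as fh:
        meta = json.load(fh)
    spec_d = dict(meta["spec"])
    spec_d["image_size"] = tuple(spec_d["image_size"])
    spec = SynthSpec(**spec_d)
    vmin, vmax = meta["vmin"], meta["vmax"]
    scale = (vmax - vmin) / 255.0 if vmax > vmin else 1.0

    labels = pd.read_csv(src / "labels.csv").set_index("sample_id")["label"]
    labs = pd.read_csv(src / "labs.csv")
    feat_cols = [c for c in labs.columns if c.startswith("f")]
    samples = []
    for sid, lab in labs.groupby("sample_id", sort=True):
        arr = np.array(Image.open(src / "images" / f"{sid}.png"), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        img = arr * scale + vmin
        series = lab.sort_values("time_index")[feat_cols].to_numpy(dtype=np.float64)
        samples.append(MultimodalSample(sample_id=str(sid), image=img, lab=series, label=int(labels[sid])))
    n_red = spec.n_redundant
    return SyntheticDataset(
        samples=samples,
        spec=spec,
        informative_dims=np.arange(spec.K - n_red),
        redundant_dims=np.arange(spec.K - n_red, spec.K),
    )
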
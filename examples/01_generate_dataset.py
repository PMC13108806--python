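"""Generate a synthetic paired image + laboratory dataset and inspect it.

Builds the strong-signal preset (600 samples, 4 classes, 32x32x3 images,
T=10 time steps, K=8 lab dims of which 4 are pure noise), prints the class
balance and a per-dimension class-separation summary, and writes the
on-disk layout (images/ + labs.csv + labels.csv) next to this script.
"""

import numpy as np

from cmapfusion import generate_dataset, preset, write_dataset

cfg = preset("toy")
dataset = generate_dataset(cfg.data)

labels = dataset.labels
print(f"{len(dataset)} samples, class counts: {np.bincount(labels).tolist()}")
print(f"informative lab dims: {dataset.informative_dims.tolist()}, "
      f"pure-noise dims: {dataset.redundant_dims.tolist()}")

labs = np.stack([s.lab for s in dataset])
for k in range(cfg.data.K):
    class_means = np.stack([labs[labels == c, :, k].mean(axis=0) for c in range(4)])
    within = np.mean([labs[labels == c, :, k].var() for c in range(4)])
    sep = class_means.var(axis=0).mean() / within
    kind = "signal" if k in dataset.informative_dims else "noise"
    print(f"  lab dim {k} ({kind}): between/within class variance ratio = {sep:.3f}")
# signal dims show ratios well above 1 (planted class profiles);
# noise dims sit near 0 (nothing to find).

path = write_dataset(dataset, "scratch_dataset")
print(f"wrote dataset layout to {path}/")
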
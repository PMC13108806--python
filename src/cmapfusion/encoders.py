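"""Modality encoders producing dimension-aligned d-vectors.

Image path: the image is cut into non-overlapping P x P patches (row-major,
top-left origin), each flattened patch is linearly embedded to d, a
learnable class token is prepended and a learnable position embedding added,
and the token sequence runs through pre-norm transformer encoder blocks;
the final class-token state is the image feature F_I.

Lab path: the T x K series is mapped per time step through a two-layer
ReLU MLP (K -> d/2 -> d, both layers ReLU) and mean-pooled over time,
yielding F_L >= 0 elementwise. The per-time-step weights keep the
(K, d/2) / (d/2, d) shapes of the written form; pooling over T is the
package's reduction of the matrix input to a single vector.

A small strided convolutional encoder with matched output dimension serves
as the image-path substitute in ablation runs; its convolutions are
non-overlapping (stride = kernel), so each stage is a patch reshape
followed by a linear map.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .errors import ConfigurationError, ShapeError
from .nn import LayerNorm, Linear, Module, Parameter, TransformerBlock

__all__ = [
    "patchify",
    "unpatchify",
    "embed_patches",
    "ViTImageEncoder",
    "ConvImageEncoder",
    "LabEncoder",
]


# ------------------------------------------------------------- functional ops

def patchify(image: np.ndarray, patch: int) -> np.ndarray:
    """Split (H, W, C) into (N, P, P, C) non-overlapping patches, row-major."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h % patch:
        raise ShapeError(f"image height {h} not divisible by patch size {patch}")
    if w % patch:
        raise ShapeError(f"image width {w} not divisible by patch size {patch}")
    c = image.shape[2]
    grid = image.reshape(h // patch, patch, w // patch, patch, c)
    return grid.transpose(0, 2, 1, 3, 4).reshape(-1, patch, patch, c)


def unpatchify(patches: np.ndarray, image_hw: tuple) -> np.ndarray:
    """Inverse of :func:`patchify`; bit-exact round trip."""
    h, w = image_hw
    n, p, _, c = patches.shape
    grid = patches.reshape(h // p, w // p, p, p, c)
    return grid.transpose(0, 2, 1, 3, 4).reshape(h, w, c)


def embed_patches(
    patches: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    e_pos: np.ndarray,
    x_cls: np.ndarray,
) -> np.ndarray:
    """Reference patch embedding: flatten, linear map to d, prepend the class
    token, add the position embedding. Returns (N+1, d)."""
    n = patches.shape[0]
    flat = patches.reshape(n, -1)
    if w.shape[0] != flat.shape[1]:
        raise ConfigurationError(
            f"embedding weight expects flattened patch length {w.shape[0]}, got {flat.shape[1]}"
        )
    tokens = flat @ w + b
    seq = np.concatenate([np.asarray(x_cls)[None, :], tokens], axis=0)
    if e_pos.shape != seq.shape:
        raise ConfigurationError(f"position embedding shape {e_pos.shape} != sequence shape {seq.shape}")
    return seq + e_pos


# ------------------------------------------------------------------- modules

class ViTImageEncoder(Module):
    """Patch-token transformer encoder; F_I is the final class-token state."""

    def __init__(
        self,
        image_size: tuple,
        patch: int,
        d: int,
        depth: int,
        heads: int,
        mlp_ratio: float,
        rng: np.random.Generator,
    ):
        h, w, c = image_size
        if h % patch or w % patch:
            raise ConfigurationError(f"image {h}x{w} not divisible by patch {patch}")
        self.image_size = tuple(image_size)
        self.patch = patch
        self.d = d
        self.n_patches = (h // patch) * (w // patch)
        patch_dim = patch * patch * c
        self.embed = Linear(patch_dim, d, rng)
        self.cls_token = Parameter(np.zeros(d))
        self.pos_embed = Parameter(
            rng.normal(0.0, 0.02, size=(self.n_patches + 1, d))
        )
        self.blocks = [TransformerBlock(d, heads, mlp_ratio, rng) for _ in range(depth)]

    def tokens(self, images: np.ndarray) -> Tensor:
        """Embedded token sequence X_emb for a batch (B, H, W, C)."""
        b = images.shape[0]
        p = self.patch
        h, w, c = self.image_size
        if images.shape[1:] != (h, w, c):
            raise ShapeError(f"expected images of shape {(h, w, c)}, got {images.shape[1:]}")
        grid = images.reshape(b, h // p, p, w // p, p, c)
        flat = grid.transpose(0, 1, 3, 2, 4, 5).reshape(b, self.n_patches, p * p * c)
        tok = self.embed(Tensor(flat))  # (B, N, d)
        cls = self.cls_token.reshape(1, 1, self.d) * Tensor(np.ones((b, 1, 1)))
        seq = concat([cls, tok], axis=1)
        return seq + self.pos_embed

    def __call__(self, images: np.ndarray) -> Tensor:
        x = self.tokens(images)
        for blk in self.blocks:
            x = blk(x)
        return x[:, 0, :]  # class token

    def flops(self) -> dict:
        n_tok = self.n_patches + 1
        out = {"patch_embed": self.embed.flops(self.n_patches)["linear"]}
        for i, blk in enumerate(self.blocks):
            out[f"block_{i}"] = blk.flops(n_tok)["transformer_block"]
        return out


class ConvImageEncoder(Module):
    """Three-stage strided (non-overlapping) convolutional encoder used by the
    image-transformer ablation; global average pool then linear to d."""

    STAGES = ((4, 32), (2, 64), (2, 128))  # (kernel=stride, channels)

    def __init__(self, image_size: tuple, d: int, rng: np.random.Generator):
        h, w, c = image_size
        factor = int(np.prod([k for k, _ in self.STAGES]))
        if h % factor or w % factor:
            raise ConfigurationError(
                f"conv encoder needs image dims divisible by {factor}, got {h}x{w}"
            )
        self.image_size = tuple(image_size)
        self.d = d
        chans = [c] + [ch for _, ch in self.STAGES]
        self.convs = [
            Linear(k * k * chans[i], chans[i + 1], rng)
            for i, (k, _) in enumerate(self.STAGES)
        ]
        self.head = Linear(chans[-1], d, rng)

    @staticmethod
    def _window(x: Tensor, k: int) -> Tensor:
        # (B, H, W, C) -> (B, H/k, W/k, k*k*C) via reshape/transpose only
        b, h, w, c = x.shape
        g = x.reshape(b, h // k, k, w // k, k, c)
        return g.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // k, w // k, k * k * c)

    def __call__(self, images: np.ndarray) -> Tensor:
        x = Tensor(images)
        for (k, _), conv in zip(self.STAGES, self.convs):
            x = conv(self._window(x, k)).relu()
        pooled = x.mean(axis=(1, 2))  # (B, channels)
        return self.head(pooled)

    def flops(self) -> dict:
        h, w, _ = self.image_size
        out = {}
        for i, ((k, _), conv) in enumerate(zip(self.STAGES, self.convs)):
            h, w = h // k, w // k
            out[f"conv_{i}"] = conv.flops(h * w)["linear"]
        out["conv_head"] = self.head.flops()["linear"]
        return out


class LabEncoder(Module):
    """Per-time-step two-layer ReLU MLP (K -> hidden -> d), mean-pooled over
    T. Output is nonnegative elementwise (outer ReLU)."""

    def __init__(self, k: int, d: int, rng: np.random.Generator, hidden: int | None = None):
        self.k = k
        self.d = d
        self.hidden = hidden if hidden is not None else d // 2
        self.fc1 = Linear(k, self.hidden, rng)
        self.fc2 = Linear(self.hidden, d, rng)

    def __call__(self, series: np.ndarray) -> Tensor:
        series = np.asarray(series, dtype=np.float64)
        if series.shape[-1] != self.k:
            raise ConfigurationError(
                f"lab encoder expects K={self.k} features, got {series.shape[-1]}"
            )
        x = Tensor(series)  # (B, T, K) or (T, K)
        h = self.fc2(self.fc1(x).relu()).relu()  # (..., T, d)
        return h.mean(axis=-2)

    def flops(self, t: int | None = None) -> dict:
        t = t if t is not None else 1
        return {
            "lab_fc1": self.fc1.flops(t)["linear"],
            "lab_fc2": self.fc2.flops(t)["linear"],
        }
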
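"""Run configuration: dataclasses, YAML loading, and named presets.

The configuration tree mirrors the framework's module structure::

    data:       synthetic-dataset spec (sizes, planted signal, redundancy)
    model:      encoder dimensions (embed dim d, patch size, depth, heads)
    smarttrim:  pruning-gate settings (lambda, relaxation temperature, toggle)
    fusion:     cross-modal attention settings (toggle, tokens-per-branch)
    train:      optimisation schedule (batch size, warmup/cosine LR, early stop)

Two presets ship with the package: ``"toy"`` — the desk-scale configuration
every test and experiment protocol runs on (d=64, depth 2, 32x32 images) —
and ``"full"`` — the full-scale geometry (d=768, depth 12, 224x224 patches of
16), constructible but not exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError, InvalidSpecError

__all__ = [
    "SynthSpec",
    "ModelConfig",
    "SmartTrimConfig",
    "FusionConfig",
    "TrainConfig",
    "RunConfig",
    "load_config",
    "preset",
]


@dataclass
class SynthSpec:
    """Specification of a synthetic paired image + lab time-series dataset.

    ``signal_strength`` is the amplitude of the class motifs in units of the
    background noise standard deviation (noise sd is 1); ``cross_modal_coupling``
    weights a per-sample shared latent injected into both modalities;
    ``redundant_fraction`` of the K lab dimensions carry pure noise.
    """

    n_samples: int = 600
    n_classes: int = 4
    image_size: tuple = (32, 32, 3)
    T: int = 10
    K: int = 8
    signal_strength: float = 3.0
    cross_modal_coupling: float = 0.8
    redundant_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_classes <= 0:
            raise InvalidSpecError("n_samples and n_classes must be positive")
        if not (0.0 <= self.cross_modal_coupling <= 1.0):
            raise InvalidSpecError("cross_modal_coupling must lie in [0, 1]")
        if not (0.0 <= self.redundant_fraction < 1.0):
            raise InvalidSpecError("redundant_fraction must lie in [0, 1)")
        if self.signal_strength < 0:
            raise InvalidSpecError("signal_strength must be nonnegative")
        if self.T < 2 or self.K < 1:
            raise InvalidSpecError("need T >= 2 time steps and K >= 1 lab dims")

    @property
    def n_redundant(self) -> int:
        return int(round(self.redundant_fraction * self.K))


@dataclass
class ModelConfig:
    d: int = 64
    patch: int = 16
    depth: int = 2
    heads: int = 4
    mlp_ratio: float = 4.0
    lab_hidden: int | None = None  # defaults to d // 2
    image_size: tuple = (32, 32, 3)
    n_classes: int = 4
    T: int = 10
    K: int = 8

    def __post_init__(self):
        if self.d % self.heads != 0:
            raise ConfigurationError(f"d={self.d} not divisible by heads={self.heads}")
        h, w, _ = self.image_size
        if h % self.patch or w % self.patch:
            raise ConfigurationError(
                f"image size {h}x{w} not divisible by patch size {self.patch}"
            )
        if self.lab_hidden is None:
            self.lab_hidden = self.d // 2

    @property
    def bottleneck(self) -> int:
        return max(4, self.d // 2)


@dataclass
class SmartTrimConfig:
    lam: float = 0.3
    temperature: float = 0.1
    enabled: bool = True


@dataclass
class FusionConfig:
    enabled: bool = True
    tokens: int = 8  # tokens per branch in token mode; 1 = literal vector mode
    heads: int = 1


@dataclass
class TrainConfig:
    batch_size: int = 32
    lr_init: float = 1e-4
    lr_final: float = 1e-6
    warmup_epochs: int = 5
    max_epochs: int = 30
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    patience: int = 10
    alpha: float = 0.1  # cross-modal alignment loss weight
    beta: float = 0.05  # sparsity loss weight
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.max_epochs:
            raise ConfigurationError("warmup_epochs must be < max_epochs")
        if min(self.lr_init, self.lr_final) <= 0:
            raise ConfigurationError("learning rates must be positive")


@dataclass
class RunConfig:
    data: SynthSpec = field(default_factory=SynthSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    smarttrim: SmartTrimConfig = field(default_factory=SmartTrimConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        # keep model geometry consistent with the dataset spec
        self.model.image_size = tuple(self.data.image_size)
        self.model.n_classes = self.data.n_classes
        self.model.T = self.data.T
        self.model.K = self.data.K

    def to_dict(self) -> dict:
        return asdict(self)


_KEY_ALIASES = {"lambda": "lam", "coupling": "cross_modal_coupling"}


def _build_section(cls, mapping: dict):
    kwargs = {}
    for key, val in mapping.items():
        key = _KEY_ALIASES.get(key, key)
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file and/or an override mapping.

    YAML keys follow the section names (``data``, ``model``, ``smarttrim``,
    ``fusion``, ``train``); ``smarttrim.lambda`` and ``data.coupling`` are
    accepted as aliases for the dataclass field names.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)
    sections = {
        "data": SynthSpec,
        "model": ModelConfig,
        "smarttrim": SmartTrimConfig,
        "fusion": FusionConfig,
        "train": TrainConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name])
    return RunConfig(**kwargs)


def preset(name: str = "toy") -> RunConfig:
    """Named configurations.

    ``toy``   — strong-signal desk-scale preset: 600 samples, 4 classes,
                32x32x3 images, T=10, K=8, coupling 0.8, half the lab dims
                redundant; model d=64, depth 2, heads 4.
    ``full``  — full-scale geometry (224x224 images, d=768, depth 12,
                heads 12, 100 epochs); constructible, not used in tests.
    """
    if name == "toy":
        return RunConfig()
    if name == "full":
        return RunConfig(
            data=SynthSpec(n_samples=600, n_classes=4, image_size=(224, 224, 3)),
            model=ModelConfig(d=768, patch=16, depth=12, heads=12, image_size=(224, 224, 3)),
            train=TrainConfig(max_epochs=100),
        )
    raise ConfigurationError(f"unknown preset {name!r}")
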
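"""Exception types shared across the package."""


class CmapFusionError(Exception):
    """Base class for package errors."""


class ConfigurationError(CmapFusionError, ValueError):
    """Inconsistent model/run configuration (weight shape mismatch, bad dims)."""


class ShapeError(CmapFusionError, ValueError):
    """Array shape violates an operation's precondition."""


class InvalidSpecError(CmapFusionError, ValueError):
    """Synthetic dataset specification violates its invariants."""


class UndefinedMetricError(CmapFusionError, ValueError):
    """The requested metric is undefined on the given input."""
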
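"""Exception hierarchy shared across the package."""


class TrajselError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrajselError):
    """Invalid generator, split or training configuration."""


class LabelingError(TrajselError):
    """Unknown ligand id or class tag during label assignment."""


class FeaturizationError(TrajselError):
    """Bad atom indices or degenerate geometry while computing descriptors."""


class UnsupportedArchitectureError(TrajselError):
    """A saliency method was requested for a model lacking the required structure."""
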
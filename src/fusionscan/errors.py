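"""Exception hierarchy shared across the pipeline."""


class FusionscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FusionscanError):
    """Invalid or inconsistent run configuration."""


class NewickError(FusionscanError):
    """Malformed or unusable phylogeny input."""


class HitTableError(FusionscanError):
    """Malformed tabular alignment input."""


class CoordinateError(FusionscanError):
    """Coordinates outside the range allowed by the referenced sequence."""


class PlanError(FusionscanError):
    """Invalid simulation plan."""


class StageError(FusionscanError):
    """A pipeline stage is missing its upstream inputs."""
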
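"""Exception hierarchy shared across the package."""


class MceNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MceNetError):
    """A file could not be parsed as an expression matrix or network."""


class ValidationError(MceNetError):
    """Data violated an invariant (out-of-alphabet value, duplicate gene, ...)."""


class AlignmentError(MceNetError):
    """Vectors or views that must share a sample axis do not."""


class InsufficientSamplesError(MceNetError):
    """Too few samples for the requested operation (lagging, z-scoring)."""


class ConfigurationError(MceNetError):
    """An invalid parameter combination (segment sizes, worker counts, ...)."""


class DistributionError(MceNetError):
    """A probability vector is negative or does not sum to one."""
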
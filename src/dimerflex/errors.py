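"""Exception hierarchy.

Every error raised on purpose by this package derives from DimerflexError so
callers (and the CLI) can separate expected failures from bugs.
"""


class DimerflexError(Exception):
    """Base class for all package errors."""


class FormatError(DimerflexError):
    """A structure or table file could not be parsed."""


class EmptyModelError(DimerflexError):
    """A structure contains no atoms (or no usable atoms for the request)."""


class ResidueLookupError(DimerflexError):
    """A chain or residue requested by identifier does not exist."""


class CorrespondenceError(DimerflexError):
    """Two chains could not be paired residue-by-residue."""


class GeometryError(DimerflexError):
    """A geometric operation received degenerate input (n < 3, collinear...)."""


class ConfigError(DimerflexError):
    """Thresholds or options are malformed (wrong order, non-positive...)."""


class FitError(DimerflexError):
    """A model fit failed or its preconditions were violated."""


class GenerationError(DimerflexError):
    """A synthetic-structure spec is unsatisfiable."""
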
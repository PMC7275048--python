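"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`IntronToggleError`, so callers can catch package failures without
masking programming errors.
"""


class IntronToggleError(Exception):
    """Base class for all errors raised by introntoggle."""


class FormatError(IntronToggleError):
    """A file does not conform to the expected text format."""


class NotFoundError(IntronToggleError):
    """A requested model, atom, or file component is absent."""


class ConsistencyError(IntronToggleError):
    """Inputs that must agree (atom counts, time axes) do not."""


class SelectionError(IntronToggleError):
    """A selection expression is malformed or resolves unexpectedly."""


class DimensionError(IntronToggleError):
    """Coordinate sets with incompatible shapes."""


class DescriptorError(IntronToggleError):
    """A geometric descriptor cannot be evaluated (e.g. missing ring atom)."""


class ParameterError(IntronToggleError):
    """A parameter value is outside its meaningful domain."""


class SummaryError(IntronToggleError):
    """Too few frames remain to summarize a series."""


class MappingError(IntronToggleError):
    """Atom correspondence between two conformations failed."""


class ResampleError(IntronToggleError):
    """A path cannot be resampled at the requested node count."""


class ConfigurationError(IntronToggleError):
    """A required configuration value is missing or inconsistent."""


class ReconstructionError(IntronToggleError):
    """A free-energy surface cannot be reconstructed."""


class BasinError(IntronToggleError):
    """No free-energy minimum exists in a hinted basin region."""


class SamplerError(IntronToggleError):
    """The toy Langevin sampler diverged."""


class FitError(IntronToggleError):
    """Nonlinear fitting failed to converge."""


class ConstructionError(IntronToggleError):
    """A synthetic geometry target is infeasible."""
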
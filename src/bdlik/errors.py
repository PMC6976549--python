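"""Exception hierarchy.

All package-specific failures derive from :class:`BdlikError` so callers can
catch numerical problems separately from programming errors.
"""


class BdlikError(Exception):
    """Base class for all package errors."""


class DomainError(BdlikError, ValueError):
    """A parameter is outside its admissible domain (e.g. a negative rate)."""


class OrderingError(BdlikError, ValueError):
    """Time arguments violate the required ordering (past -> present)."""


class UnsupportedModelError(BdlikError, TypeError):
    """The rate model lacks a property the operation requires
    (e.g. diversity independence for the Kendall functions)."""


class NumericalConsistencyError(BdlikError, ArithmeticError):
    """Two mathematically equivalent evaluation routes disagree beyond
    the permitted numerical tolerance."""


class TruncationError(BdlikError, ArithmeticError):
    """A truncated vector or series carries too much mass at its tail;
    retry with a larger truncation."""


class NumericalError(BdlikError, ArithmeticError):
    """An ODE solver or quadrature routine failed to converge."""


class ResourceError(BdlikError, RuntimeError):
    """An adaptive procedure hit its hard resource cap without converging."""


class FormatError(BdlikError, ValueError):
    """Malformed input data (e.g. a non-ultrametric or non-binary tree)."""


class ConfigError(BdlikError, ValueError):
    """Invalid run configuration."""
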
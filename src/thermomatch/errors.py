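"""Exception hierarchy.

The CLI maps these onto distinct exit codes: input/configuration problems,
model non-convergence, and everything else (internal faults).
"""


class ThermomatchError(Exception):
    """Base class for all package-specific errors."""


class InputError(ThermomatchError, ValueError):
    """Malformed or degenerate measurement data."""


class DomainError(ThermomatchError, ValueError):
    """Parameter outside its mathematical or physical domain."""


class UnitsError(ThermomatchError, ValueError):
    """Cross-unit arithmetic attempted without an explicit conversion."""


class BlockMatchingError(InputError):
    """A replicate has no control replicates from its own temporal block."""


class ConfigurationError(ThermomatchError, ValueError):
    """Invalid preset or pipeline configuration."""


class FitError(ThermomatchError, RuntimeError):
    """Model fitting failed or the data cannot support the requested model."""
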
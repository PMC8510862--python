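"""Exception and warning types shared across the package."""


class ClotlyseError(Exception):
    """Base class for all package-specific errors."""


class InvalidTraceError(ClotlyseError):
    """A turbidity trace violates its invariants (grid, length, finiteness)."""


class DegenerateTraceError(ClotlyseError):
    """A trace cannot be normalized (constant signal, max == min)."""


class RegimeDetectionError(ClotlyseError):
    """A lysis regime boundary could not be located on the curve."""


class NoLysisError(RegimeDetectionError):
    """The curve never leaves the slow-fit window; no lysis detectable."""


class InsufficientWindowError(RegimeDetectionError):
    """Fewer than 3 samples fall inside the slow-regime fit window."""


class InvalidStateError(ClotlyseError):
    """A kinetic state vector violates non-negativity or capacity bounds."""


class UnitConversionError(ClotlyseError):
    """Unknown species or missing molecular weight in a unit conversion."""


class SolverError(ClotlyseError):
    """Numerical integration failed; carries solver diagnostics."""


class ConfigError(ClotlyseError):
    """Inconsistent or incomplete configuration."""


class NoLysisWarning(UserWarning):
    """Turbidity minimum sits at the final sample: lysis never started."""


class TruncatedLysisWarning(UserWarning):
    """Derivative maximum at the last sample: lysis not finished in-trace."""
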
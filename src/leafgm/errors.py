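"""Exception hierarchy shared across the package."""


class LeafGMError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LeafGMError, ValueError):
    """An input violates a physical or numeric precondition."""


class FitFailureError(LeafGMError, RuntimeError):
    """A curve fit did not converge within the multistart budget."""


class SingularPointError(LeafGMError, ValueError):
    """The variable-J inversion hit the pole J_F = 4(A + Rd)."""


class MalformedCycleError(LeafGMError, ValueError):
    """A TDL measurement cycle is missing or duplicating a valve stream."""


class CalibrationFailureError(LeafGMError, RuntimeError):
    """Span responses are non-monotone or otherwise unusable."""


class UndefinedDiscriminationError(LeafGMError, ValueError):
    """No CO2 drawdown across the chamber: discrimination is undefined."""


class NonphysicalPartitionError(LeafGMError, ValueError):
    """Series subtraction of conductances produced a non-positive component."""


class MissingOperatingPointError(LeafGMError, ValueError):
    """No logged point near the requested reference CO2 setpoint."""


class SchemaError(LeafGMError, ValueError):
    """An input table is missing a mandatory column."""


class ConfigurationError(LeafGMError, ValueError):
    """Pipeline configuration is incomplete or inconsistent."""
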
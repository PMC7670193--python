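"""Exception hierarchy.

Validation problems (bad geometry, malformed config, schema violations)
derive from :class:`ValidationError`; numerical failures (root solves,
regressions) derive from :class:`NumericalError`.  The CLI maps the former
to exit code 2 and the latter to exit code 3.
"""


class BlisterDryError(Exception):
    """Base class for all package errors."""


class ValidationError(BlisterDryError, ValueError):
    """Invalid input: geometry, config, trace schema, domain violations."""


class GeometryError(ValidationError):
    """Inconsistent or out-of-domain blister geometry."""


class ConfigError(ValidationError):
    """Configuration file does not satisfy the schema."""


class TraceError(ValidationError):
    """Process-trace data fails schema or monotonicity checks."""


class NumericalError(BlisterDryError, RuntimeError):
    """Failure of a numerical procedure (root solve, regression)."""


class SolverError(NumericalError):
    """The quasi-steady interface solver could not converge."""


class FitError(NumericalError):
    """A nonlinear regression failed or produced an invalid model."""


class EstimationError(NumericalError):
    """An estimation pipeline received physically unusable data."""


class EndpointError(EstimationError):
    """No drying endpoint could be detected in a pressure-ratio trace."""
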
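"""Exception hierarchy.

Every error raised by the library derives from :class:`QuadPoissonError`,
so callers (and the CLI) can distinguish library failures from bugs.
"""


class QuadPoissonError(Exception):
    """Base class for all quadpoisson errors."""


class SchemaError(QuadPoissonError):
    """Malformed input file: missing columns, wrong marker count, bad labels."""


class InvalidObservationError(QuadPoissonError):
    """A stage/camera observation contains non-finite coordinates."""


class CalibrationDataError(QuadPoissonError):
    """Not enough (or degenerate) data to estimate the stage-camera angle."""


class InvalidQuadError(QuadPoissonError):
    """Marker quadrilateral violates its invariants (degenerate, self-intersecting)."""


class DegenerateElementError(QuadPoissonError):
    """Element Jacobian is non-positive at the requested evaluation point."""


class UndeformedSpecimenError(QuadPoissonError):
    """Maximum principal strain is below tolerance: Poisson's ratio undefined."""


class NaiveMethodError(QuadPoissonError):
    """Axis-projected baseline inapplicable (marker coordinate too close to a loading axis)."""


class ConfigurationError(QuadPoissonError):
    """Unknown strain measure, evaluation mode, or invalid parameter value."""


class FieldOfViewError(QuadPoissonError):
    """A marker falls outside the synthetic camera's field of view margin."""


class NoMarkerError(QuadPoissonError):
    """Spot detection found no connected component above threshold."""


class GenerationError(QuadPoissonError):
    """Synthetic-geometry generation exhausted its retry budget."""
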
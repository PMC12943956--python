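"""Exception hierarchy.

The CLI maps these onto exit codes: validation problems (bad schema, bad
parameters, malformed files) exit 2, data problems (degenerate geometry,
unusable trajectories) exit 3, and a degenerate baseline (zero distance
spread, so Z-scores are undefined) exits 4.
"""


class MotionScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(MotionScoreError):
    """Input violates a schema or contract (exit code 2)."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class ParameterError(ValidationError):
    """A numeric or enum parameter is out of its legal range."""


class DataError(MotionScoreError):
    """Input data is structurally valid but unusable (exit code 3)."""


class DegenerateGeometryError(DataError):
    """A joint-angle vector has zero magnitude; message names frame/landmark."""


class StatisticsError(DataError):
    """A statistical comparison was requested on groups too small to test."""


class DegenerateBaselineError(MotionScoreError):
    """Baseline distance SD is zero, so Z-scores are undefined (exit code 4)."""
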
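"""Exception hierarchy for the gradloc pipeline."""


class GradlocError(Exception):
    """Base class for all gradloc errors."""


class FormatError(GradlocError):
    """An input file violates the expected tabular format."""


class ValidationError(GradlocError):
    """Data violate a structural contract (negative signals, empty intersections, ...)."""


class ConfigurationError(GradlocError):
    """A configuration value is missing or out of range."""


class CalibrationError(GradlocError):
    """Benchmark-based calibration failed (empty groups, inverted cutoffs, unmappable clusters)."""


class ConvergenceError(GradlocError):
    """An iterative fit failed to converge within its iteration budget."""
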
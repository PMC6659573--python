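"""Exception taxonomy shared across the pipeline."""


class MotionErpError(Exception):
    """Base class for all package errors."""


class ConfigError(MotionErpError):
    """Invalid configuration value or unknown configuration key."""


class ParseError(MotionErpError):
    """Malformed on-disk file.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number in the offending file, when known.
    """

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class MontageError(MotionErpError):
    """Electrode label cannot be resolved or positions are degenerate."""


class QualityError(MotionErpError):
    """Data quality below the pipeline's hard floor (e.g. too many bad
    channels, too few surviving trials)."""


class DegenerateBaselineError(MotionErpError):
    """EMG baseline has zero variance; the 3-SD onset rule is undefined."""
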
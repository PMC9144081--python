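"""Error taxonomy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 1, data errors -> 2,
calibration failures -> 3.
"""


class EnpError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(EnpError):
    """Caller violated a precondition (bad arguments, empty input)."""

    exit_code = 1


class StructuralError(EnpError):
    """Input is structurally malformed (missing cell/region, bad schema)."""

    exit_code = 2


class DataError(EnpError):
    """Input values are invalid (NaN, out-of-range, degenerate)."""

    exit_code = 2


class CalibrationError(EnpError):
    """Tare/self-check failed: the plate is not stable enough to zero."""

    exit_code = 3
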
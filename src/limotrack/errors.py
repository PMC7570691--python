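"""Exception hierarchy shared across the package."""


class LimotrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(LimotrackError, ValueError):
    """An argument violated a documented precondition."""


class InconsistentProportionsError(InvalidArgumentError):
    """A custom proportion table whose vertical chain does not sum to 7.5."""


class EmptyCloudError(LimotrackError):
    """An operation requiring points received an empty cloud."""


class FrameMismatchError(LimotrackError):
    """Two clouds expected in the same coordinate frame were not."""


class DegenerateGeometryError(LimotrackError):
    """Geometry made a formula undefined (e.g. vertical reference line)."""


class AlreadyAlignedError(LimotrackError):
    """Refused to align a quaternion stream twice."""


class MissingSensorError(LimotrackError):
    """A sensed segment required to derive others has no data."""

    def __init__(self, segment: str):
        self.segment = segment
        super().__init__(f"missing sensed segment required for derivation: {segment}")


class InsufficientTrackError(LimotrackError):
    """Fewer than two samples available for interpolation."""


class AlignmentError(LimotrackError):
    """Timestamp grids could not be aligned within tolerance."""


class InvalidWindowError(LimotrackError):
    """An evaluation window is empty or out of range."""


class ParseError(LimotrackError):
    """A file failed to parse; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnsupportedFormatError(LimotrackError):
    """File extension/format not handled."""


class SchemaError(LimotrackError):
    """Tabular input had unexpected columns or values."""
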
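"""Exception types shared across the pipeline."""


class NucTensionError(Exception):
    """Base class for all pipeline errors."""


class PlacementError(NucTensionError):
    """Synthetic objects could not be placed under the configured constraints."""


class CalibrationError(NucTensionError):
    """Bleed-through calibration failed (e.g. too few valid pixels)."""


class BandError(NucTensionError):
    """A nuclear-envelope band could not be constructed for a nucleus."""


class UnresolvedProfileError(NucTensionError):
    """An axial profile does not contain two resolvable peaks."""


class BedParseError(NucTensionError):
    """A BED line failed validation; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
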
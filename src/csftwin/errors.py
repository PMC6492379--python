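"""Exception hierarchy for the csftwin package."""


class CsfTwinError(Exception):
    """Base class for all csftwin errors."""


class InvalidParameterError(CsfTwinError, ValueError):
    """A parameter value violates its documented domain."""


class GridMismatchError(CsfTwinError):
    """Two waveforms that must share a sampling grid do not."""


class PhysicalStateError(CsfTwinError):
    """A gas-law state variable (pressure/volume) left its physical domain."""


class ConfigError(CsfTwinError):
    """Configuration file is missing, contradictory or invalid."""


class FormatError(CsfTwinError):
    """A CSV/JSON input file violates the documented format."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class OpenProfileError(CsfTwinError):
    """Cam synthesis asked for a profile that does not close (net volume != 0)."""


class DriftError(CsfTwinError):
    """Pump waveform carries net volume per cycle; simulation would drift."""


class CannotSplitError(CsfTwinError):
    """Too few cycle boundaries detected to split a recording."""
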
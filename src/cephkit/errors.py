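"""Exception hierarchy shared across cephkit modules."""


class CephkitError(Exception):
    """Base class for all cephkit domain errors."""


class InvalidInputError(CephkitError, ValueError):
    """A value violates a precondition (non-finite coordinate, bad parameter)."""


class DegenerateSegmentError(InvalidInputError):
    """A slope or angle was requested for a zero-length segment or ray."""


class InvalidCalibrationError(InvalidInputError):
    """A calibration specification cannot convert pixels to physical units."""


class MissingLandmarkError(CephkitError, KeyError):
    """A measurement requires landmarks absent from the landmark set."""

    def __init__(self, codes):
        self.codes = tuple(codes)
        super().__init__(", ".join(self.codes))

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return f"missing landmark(s): {', '.join(self.codes)}"


class UnknownLandmarkError(CephkitError, ValueError):
    """A landmark file names a code outside the 11-landmark registry."""


class LandmarkFileError(CephkitError, ValueError):
    """A landmark coordinate file is malformed."""


class InsufficientDataError(CephkitError, ValueError):
    """A statistical operation was requested on too few observations."""


class IncompleteReportError(CephkitError, ValueError):
    """A case report is missing required measurements."""
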
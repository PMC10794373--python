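"""Exception hierarchy for the vrepm pipeline."""


class VrepmError(Exception):
    """Base class for all vrepm errors."""


class FormatError(VrepmError):
    """An input file does not match the declared format (missing columns etc.)."""


class DataError(VrepmError):
    """A file parses but its content violates a data contract (non-monotone time etc.)."""


class InsufficientDataError(VrepmError):
    """Too few samples / subjects for the requested operation."""


class CalibrationError(VrepmError):
    """Invalid calibration transform (non-orthonormal rotation)."""


class UsageError(VrepmError):
    """The operation was called on an object in the wrong state."""


class DesignError(VrepmError):
    """A statistical design requirement is violated (e.g. too few subjects per group)."""


class IncompatibleMapsError(VrepmError):
    """Occupancy maps with different geometry were combined."""
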
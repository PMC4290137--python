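"""Exception types shared across the package."""


class VesselSegError(Exception):
    """Base class for package errors."""


class FormatError(VesselSegError):
    """A file could not be read or written in the requested format."""


class AmbiguousSeriesError(FormatError):
    """A DICOM directory contains more than one image series."""


class ParameterError(VesselSegError, ValueError):
    """An invalid parameter value was supplied."""


class DegenerateInterfaceError(VesselSegError):
    """A level-set field has no zero crossing (all-inside or all-outside).

    Carries ``iteration`` when raised from inside the evolution loop.
    """

    def __init__(self, msg: str, iteration: int | None = None):
        super().__init__(msg)
        self.iteration = iteration


class NumericalFailureError(VesselSegError):
    """Non-finite values appeared during evolution."""

    def __init__(self, msg: str, iteration: int | None = None):
        super().__init__(msg)
        self.iteration = iteration
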
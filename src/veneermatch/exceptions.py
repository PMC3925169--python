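"""Exception and warning types shared across the package."""


class VeneerMatchError(Exception):
    """Base class for all veneermatch errors."""


class MeasurementError(VeneerMatchError):
    """A physical measurement violates its validity constraints."""


class LoadError(VeneerMatchError):
    """A specimen table could not be parsed or validated."""


class ImageIOError(VeneerMatchError):
    """An image file could not be read or has no pixels."""


class EmptyForegroundError(VeneerMatchError):
    """The background cutoff removed every pixel of the image."""


class UndefinedSkewnessError(VeneerMatchError):
    """The intensity distribution has no spread, so mode skewness is undefined."""


class DegenerateDataError(VeneerMatchError):
    """Input data carry no usable variation (e.g. all points identical)."""


class ParameterError(VeneerMatchError):
    """A parameter is outside its admissible range."""


class PipelineStageError(VeneerMatchError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class EvaporativeLossWarning(UserWarning):
    """Wet weight below dry weight: likely evaporative loss between weighings."""


class DegenerateTestWarning(UserWarning):
    """All values in a statistical comparison are identical; the test is vacuous."""
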
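"""Exception types shared across the pipeline."""


class CheekmorphError(Exception):
    """Base class for all package-specific errors."""


class MissingLandmarkError(CheekmorphError):
    """A required anatomical landmark is absent or non-finite."""


class DegenerateGeometryError(CheekmorphError):
    """Landmark configuration does not define the requested frame or plane."""


class RegistrationError(CheekmorphError):
    """Surface registration could not be performed (e.g. empty mask)."""


class MeasurementError(CheekmorphError):
    """ROI clipping, volumetric subtraction or profile search failed."""


class FormatError(CheekmorphError):
    """An input file could not be parsed as a mesh or landmark set."""
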
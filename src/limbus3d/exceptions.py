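"""Exception hierarchy.

Every error raised by the package derives from :class:`Limbus3DError`, so a
caller processing a batch of eyes can catch one type and keep going.
"""


class Limbus3DError(Exception):
    """Base class for all package errors."""


# --- record / file handling ------------------------------------------------

class MissingField(Limbus3DError):
    """A required field (or mapped container key) is absent."""


class BadCalibration(Limbus3DError):
    """Pixel-to-mm calibration factor is non-positive or non-finite."""


class EmptySurface(Limbus3DError):
    """Height field contains no finite points."""


class IOFailure(Limbus3DError):
    """Reading or writing a record failed at the filesystem level."""


class SchemaMismatch(Limbus3DError):
    """A contour CSV does not follow the documented schema."""


# --- white-to-white detection ---------------------------------------------

class PeakCountError(Limbus3DError):
    """Fewer than three prominent peaks in the intensity spectrum."""


class SeedOutsideDark(Limbus3DError):
    """Seed pixel for region growing falls in the bright (scleral) class."""


class EmptyRegion(Limbus3DError):
    """No dark connected component survives at the seed."""


class DegenerateMask(Limbus3DError):
    """Binary mask too small to trace a boundary."""


# --- limbus detection ------------------------------------------------------

class InsufficientCoverage(Limbus3DError):
    """Too few polar samples are supported by the height data."""


class WindowTooWide(Limbus3DError):
    """Smoothing window exceeds the longest valid span of a meridian."""


class TooFewValidMeridians(Limbus3DError):
    """Less than the required fraction of meridians produced a limbus point."""


class AxisMeridianInvalid(Limbus3DError):
    """A cardinal meridian needed for a diameter/depth is invalid."""


# --- contour geometry ------------------------------------------------------

class DegenerateContour(Limbus3DError):
    """Fewer than three non-collinear points for a plane fit."""


class NoOverlap(Limbus3DError):
    """Two contours share no angle where both are valid."""


# --- statistics ------------------------------------------------------------

class EmptyInput(Limbus3DError):
    """Summary statistics requested for an empty sample."""


class TooFewObservations(Limbus3DError):
    """A t-test sample has fewer than two observations."""


class EmptyGroup(Limbus3DError):
    """A cohort table cell has no eyes."""


# --- synthetic data --------------------------------------------------------

class BadParameters(Limbus3DError):
    """Generator parameters cannot produce the requested feature."""
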
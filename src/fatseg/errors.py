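"""Exception hierarchy for the fatseg pipeline.

All package errors derive from :class:`FatsegError` so callers can catch the
whole family; subclasses distinguish input problems, per-slice segmentation
failures, and geometry/statistics degeneracies.
"""


class FatsegError(Exception):
    """Base class for all fatseg errors."""


class InputError(FatsegError):
    """Missing, empty, or malformed input (files, directories, arguments)."""


class MetadataError(InputError):
    """Required image metadata (e.g. pixel spacing) is absent."""


class InconsistencyError(InputError):
    """Slices within one series disagree on matrix size or spacing."""


class DimensionalityError(InputError):
    """Volume input does not have the expected number of dimensions."""


class ParameterError(FatsegError):
    """Invalid segmentation parameter (even window, window too large, ...)."""


class EmptyMaskError(FatsegError):
    """A binary mask that must contain foreground pixels is empty."""


class NoValidRegionError(FatsegError):
    """No connected component satisfies the region-consistency criteria."""


class SegmentationFailure(FatsegError):
    """Automatic segmentation failed for one slice."""


class LandmarkError(FatsegError):
    """Landmark annotation is out of range or out of order."""


class QuantificationError(FatsegError):
    """Area/volume computation impossible (e.g. every slice failed)."""


class SnapError(FatsegError):
    """A contour-edit polyline endpoint is too far from the contour."""


class GeometryError(FatsegError):
    """A contour edit cannot produce a simple closed polygon."""


class NestingViolationError(FatsegError):
    """An edit would break envelope within inner within outer nesting."""


class PhantomSpecError(FatsegError):
    """Infeasible or invalid synthetic-phantom specification."""


class DegenerateRegressionError(FatsegError):
    """Regression undefined (constant reference values)."""


class SampleSizeError(FatsegError):
    """Too few samples for the requested statistic."""


class PairingError(FatsegError):
    """Two result sets cannot be matched subject-by-subject."""
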
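"""Exception hierarchy.

All package errors derive from :class:`LVDecompError` so callers can catch one
type at pipeline boundaries; fine-grained subclasses name the failing invariant.
"""


class LVDecompError(Exception):
    """Base class for all lvdecomp errors."""


class InvalidContourError(LVDecompError):
    """Contour has fewer than 3 distinct points or non-finite coordinates."""


class DegenerateContourError(LVDecompError):
    """Contour encloses zero area (collinear points)."""


class NotStarShapedError(LVDecompError):
    """A ray from the polar center crosses the boundary zero or multiple times."""


class GridMismatchError(LVDecompError):
    """Two radial profiles do not share center and angular grid."""


class InvalidLandmarkError(LVDecompError):
    """RV insertion landmarks coincide or are ambiguous about the center."""


class EmptyStackError(LVDecompError):
    """No slice carries the requested contour."""


class InsufficientSlicesError(LVDecompError):
    """Fewer eligible slices than the operation requires."""


class NegativeStrokeVolumeError(LVDecompError):
    """ESV exceeds EDV — indicates a segmentation or frame-assignment error."""


class InvalidAxisError(LVDecompError):
    """Long-axis direction has zero norm."""


class LandmarkSetError(LVDecompError):
    """The six AV-plane landmark pairs are missing, duplicated or mislabeled."""


class InvalidAreaError(LVDecompError):
    """Basal area is non-positive."""


class NoSeptalDefinitionError(LVDecompError):
    """No slice carries RV insertion landmarks, so no septal window exists."""


class StudyValidationError(LVDecompError):
    """A CineStudy violates structural invariants (ordering, spacing, nesting)."""


class GenerationError(LVDecompError):
    """A phantom spec produced invalid (e.g. non-star-shaped) contours."""


class SchemaError(LVDecompError):
    """A dataset file violates the on-disk schema."""


class UndefinedCorrelationError(LVDecompError):
    """Correlation undefined because one variable has zero variance."""


class DecompositionError(LVDecompError):
    """Wrapper carrying the pipeline stage at which a decomposition failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
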
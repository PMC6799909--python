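"""Exception hierarchy for markermorph.

All package errors derive from :class:`MarkerMorphError` so callers can
catch everything with one clause; subclasses distinguish I/O, validation
and geometric-degeneracy failures.
"""


class MarkerMorphError(Exception):
    """Base class for all markermorph errors."""


class VolumeFormatError(MarkerMorphError):
    """A volume file could not be read or written in a supported format."""


class MetadataError(MarkerMorphError):
    """A volume file lacks required spatial metadata (affine/spacing)."""


class StudyValidationError(MarkerMorphError):
    """A study config, landmark file or marker file fails validation."""


class DegenerateGeometryError(MarkerMorphError):
    """Input point geometry is degenerate (collinear/coincident points)."""


class AmbiguityError(MarkerMorphError):
    """Two marker seeds claim the same segmented component."""


class InsufficientMarkersError(MarkerMorphError):
    """Too few bone markers observed for a rigid-body imputation."""


class IllConditionedProjectionError(MarkerMorphError):
    """A vector is (numerically) normal to the projection plane, so its
    projected angle is undefined."""


class PhantomSpecError(MarkerMorphError):
    """A synthetic-phantom specification is invalid (marker outside the
    volume, overlapping markers, non-positive dimensions...)."""


class PipelineError(MarkerMorphError):
    """A pipeline stage failed; the message names the stage and input."""
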
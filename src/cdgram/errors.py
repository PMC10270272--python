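"""Exception hierarchy for the CDG pipeline.

Every stage raises a subclass of :class:`CdgError` whose ``stage`` attribute
names the pipeline stage, so orchestration code can report which stage failed.
"""


class CdgError(Exception):
    """Base class for all pipeline errors."""

    stage = "cdgram"


class LeadSetError(CdgError):
    """A required ECG lead is missing from a record or file."""

    stage = "signal_io"


class FormatError(CdgError):
    """A file does not parse in the declared format."""

    stage = "signal_io"


class FilterSpecError(CdgError):
    """Filter specification incompatible with the sampling rate."""

    stage = "signal_io"


class NoBeatsError(CdgError):
    """No QRS complexes could be detected (e.g. flat signal)."""

    stage = "fiducials"


class FiducialError(CdgError):
    """No beat yielded a resolvable set of fiducial points."""

    stage = "fiducials"


class LatticeSizeError(CdgError):
    """RBF lattice would exceed the configured center cap."""

    stage = "cardiodynamics"


class InstabilityError(CdgError):
    """Deterministic-learning weights diverged; reduce the adaptation rate."""

    stage = "cardiodynamics"


class DegenerateTrajectoryError(CdgError):
    """Trajectory has no usable nearest-neighbor pairs (e.g. all points equal)."""

    stage = "heterogeneity"


class TrajectorySizeError(CdgError):
    """Trajectory too short for the requested divergence horizon."""

    stage = "heterogeneity"


class TrainingError(CdgError):
    """Classifier retraining input is invalid (e.g. a single class)."""

    stage = "classifier"


class LabelingError(CdgError):
    """Cohort record lacks the fields needed to apply a reference standard."""

    stage = "cohort_eval"


class SchemaError(CdgError):
    """Cohort table violates the expected schema."""

    stage = "cohort_eval"
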
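"""Exception hierarchy shared across the package."""


class PostureError(Exception):
    """Base class for all posturekit errors."""


class CaptureParseError(PostureError):
    """Skeleton capture file could not be parsed."""

    def __init__(self, message: str, frame_index: int | None = None):
        self.frame_index = frame_index
        if frame_index is not None:
            message = f"{message} (frame {frame_index})"
        super().__init__(message)


class EmptyCaptureError(PostureError):
    """Capture contains no frames with a tracked body."""


class MissingJointError(PostureError):
    """A required skeleton joint is absent."""


class UnknownLandmarkError(PostureError):
    """Landmark name not in the vocabulary for the requested view."""


class DuplicateLandmarkError(PostureError):
    """The same landmark appears more than once in a table."""


class MissingLandmarkError(PostureError):
    """An index computation lacks a required landmark."""


class UndefinedAngleError(PostureError):
    """Angle requested between coincident points."""


class RubricError(PostureError):
    """Grading rubric is malformed (gaps, overlaps, unknown grades)."""


class DegenerateModelError(PostureError):
    """Statistic undefined for this input (e.g. zero variance)."""


class ImplausiblePoseError(PostureError):
    """Requested postural deviation is outside the supported range."""
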
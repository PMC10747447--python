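"""Exception hierarchy for the mvkin pipeline.

Every stage raises a subclass of :class:`MvkinError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class MvkinError(Exception):
    """Base class for all mvkin errors."""


class ConfigurationError(MvkinError):
    """Invalid configuration value or malformed config file."""


class SchemaError(ConfigurationError):
    """Config dictionary has missing or unknown keys."""


class InsufficientViewsError(MvkinError):
    """Fewer than two usable camera observations for a 3D point."""


class DegenerateGeometryError(MvkinError):
    """Camera geometry does not determine a unique solution."""


class AlignmentError(MvkinError):
    """Frame grids or conventions of paired traces do not match."""


class TaskMismatchError(AlignmentError):
    """Two traces that should describe the same task do not."""


class NoMotionError(MvkinError):
    """A representative trace is constant; no max/min section exists."""


class DegenerateFrameError(MvkinError):
    """Keypoints are coincident/collinear and define no anatomical frame."""


class MissingKeypointError(MvkinError):
    """A required keypoint is absent from a skeleton series."""

    def __init__(self, missing, task=None):
        self.missing = tuple(missing)
        self.task = task
        msg = f"missing required keypoints: {', '.join(self.missing)}"
        if task is not None:
            msg += f" (task {task})"
        super().__init__(msg)


class UndefinedStatisticError(MvkinError):
    """A reliability statistic is undefined for the given data
    (e.g. ICC with zero between-subject variance)."""
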
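"""Exception hierarchy used across the pipeline.

Every stage raises a subclass of :class:`AutoRefError` so callers (and the
CLI) can map failures to machine-readable, stage-tagged exit codes.
"""


class AutoRefError(Exception):
    """Base class for all package errors."""

    stage = "autoref"


class FormatError(AutoRefError):
    """An image file could not be parsed (bad header, truncated payload)."""

    stage = "io"


class SeriesError(AutoRefError):
    """A DICOM series is internally inconsistent (mixed spacing/orientation)."""

    stage = "io"


class OrientationError(AutoRefError):
    """Orientation metadata is missing or ambiguous and no override was given."""

    stage = "io"


class SpecError(AutoRefError):
    """A phantom specification cannot be realized on the requested grid."""

    stage = "phantom"


class TrainingError(AutoRefError):
    """Detector training received unusable data (no positives, one class)."""

    stage = "train"


class ExtractionError(AutoRefError):
    """Reference-tissue ROI extraction failed; the case is unusable."""

    stage = "roi"


class ConfigError(AutoRefError):
    """A run configuration is invalid (schema violation, missing model)."""

    stage = "config"
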
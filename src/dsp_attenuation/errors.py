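"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can map
failures to exit codes (2 = configuration, 3 = data, 4 = stage failure).
"""


class PipelineError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 4


class ConfigError(PipelineError):
    """Invalid configuration (bad field value, missing input file)."""

    exit_code = 2


class DataError(PipelineError):
    """Malformed or inconsistent data."""

    exit_code = 3


class FormatError(DataError):
    """A file does not conform to its declared format."""


class LinkageError(DataError):
    """Count matrix and metadata cannot be joined (orphan or duplicate AOIs)."""


class DegenerateAOIError(DataError):
    """An AOI whose third-quartile count is zero cannot be Q3-normalized."""


class ContrastError(DataError):
    """A differential-expression contrast references an empty or invalid group."""


class AlignmentError(DataError):
    """Two per-gene tables do not share the same gene universe."""


class FilterError(DataError):
    """A gene filter left nothing to analyze."""


class DesignError(DataError):
    """An experimental design is unusable (e.g. a factor level with < 2 AOIs)."""
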
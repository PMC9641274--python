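"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors (2), data/format
errors (3), numerical/degenerate-input errors (4).
"""


class ThzBurnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThzBurnError):
    """Invalid parameter, grid, band or spec value."""


class FormatError(ThzBurnError):
    """Malformed on-disk container; message names the offending field."""


class IntegrityError(ThzBurnError):
    """Tabular data violates schema or uniqueness constraints."""


class AlignmentError(ThzBurnError):
    """A pixel trace could not be aligned (e.g. all-zero reference gate)."""


class GatingError(ThzBurnError):
    """The gate window would be truncated at a trace boundary."""


class DegenerateInputError(ThzBurnError):
    """Zero-energy input where a normalised quantity is required."""


class ReferenceDeconvolutionError(ThzBurnError):
    """Air reference degenerate at a selected sub-band; message names it."""


class LabelError(ThzBurnError):
    """Out-of-range histology percentage."""


class PartitionError(ThzBurnError):
    """A class has too few observations to split or stratify."""


class UndefinedMetricError(ThzBurnError):
    """Metric requested on single-class ground truth."""
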
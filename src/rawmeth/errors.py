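"""Exception hierarchy.

Every error raised by the package derives from :class:`RawmethError`, so
callers (and the CLI) can distinguish package failures from programming
errors and map them to exit codes.
"""


class RawmethError(Exception):
    """Base class for all package errors."""


class FastqParseError(RawmethError):
    """Malformed FASTQ input (bad record structure, length mismatch)."""


class AllcParseError(RawmethError):
    """Malformed per-cytosine (allC) table row."""


class EstimationError(RawmethError):
    """An estimate is undefined for the given counts (e.g. no target sites)."""


class SamplingError(RawmethError):
    """Requested subsample exceeds the available reads."""


class FitError(RawmethError):
    """Calibration model cannot be fitted (too few or degenerate points)."""


class ConfigurationError(RawmethError):
    """Invalid configuration (unknown context, bad rate, missing model...)."""
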
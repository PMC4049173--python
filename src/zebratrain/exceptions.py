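"""Exception hierarchy.

Three failure classes are distinguished so callers (and the CLI exit codes)
can react differently: bad configuration, bad input data, and metrics that
are mathematically undefined on the given train.
"""


class ZebratrainError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ZebratrainError):
    """A generator preset, analysis option or pipeline config violates its invariants."""


class ValidationError(ZebratrainError):
    """Input data (spike files, manifests, tables, waveform snippets) failed validation.

    The message names the file/row/field that violated which invariant.
    """


class UndefinedMetricError(ZebratrainError):
    """The requested statistic is undefined on this input (too few events, zero baseline, ...)."""
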
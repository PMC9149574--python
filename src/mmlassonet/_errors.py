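"""Exception hierarchy used across the package."""


class MMLassoNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MMLassoNetError, ValueError):
    """A configuration object violates its invariants."""


class InputError(MMLassoNetError, ValueError):
    """An input array/argument violates an operation's precondition."""


class DegenerateInputError(InputError):
    """Input is formally valid but makes the quantity undefined (e.g. sigma = 0)."""


class UndefinedMetricError(InputError):
    """A confusion-matrix metric has a zero denominator."""


class SplitError(InputError):
    """A dataset cannot be split as requested (e.g. a class is too small)."""


class ExportError(MMLassoNetError):
    """An output file cannot be written (e.g. missing atlas coordinates)."""
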
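"""Exception types shared across the package."""


class NLHVDMError(Exception):
    """Base class for package errors."""


class InvalidParameterError(NLHVDMError, ValueError):
    """A model parameter violates its documented domain."""


class InvalidInputError(NLHVDMError, ValueError):
    """An input array/grid violates a documented precondition."""


class InvalidConfigError(NLHVDMError, ValueError):
    """A configuration field is outside its documented range."""


class MissingProbeError(NLHVDMError, KeyError):
    """A requested probe id is absent from the dataset."""


class UndefinedRatioError(NLHVDMError, ZeroDivisionError):
    """The simulation-error ratio denominator is zero (exact fit at horizon)."""


class UndefinedNormalizationError(NLHVDMError, ZeroDivisionError):
    """A relative error is requested against an all-zero reference."""


class ParseError(NLHVDMError, ValueError):
    """A text input file is malformed; the message names the offending line."""


class InvalidPatternError(NLHVDMError, ValueError):
    """A motif pattern contains a character outside the IUPAC alphabet."""
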
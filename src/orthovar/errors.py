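"""Exception hierarchy shared across the package."""


class OrthovarError(Exception):
    """Base class for all orthovar errors."""


class FormatError(OrthovarError):
    """A file or record does not conform to the expected syntax."""


class ValidationError(OrthovarError):
    """Input is syntactically valid but violates a domain invariant."""


class BoundsError(OrthovarError, IndexError):
    """A column or position index falls outside the valid range."""


class UndefinedStatisticError(OrthovarError):
    """A statistic has an empty denominator and is undefined."""


class ConfigError(OrthovarError):
    """A simulation or pipeline configuration is inconsistent."""
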
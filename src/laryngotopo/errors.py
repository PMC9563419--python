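"""Exception hierarchy shared by all pipeline stages."""


class LTGError(Exception):
    """Base class for all laryngotopography errors."""


class InputError(LTGError, ValueError):
    """A supplied input (recording, mask, landmark set) is invalid."""


class FormatError(LTGError, IOError):
    """A container or file could not be parsed."""


class ConfigurationError(LTGError, ValueError):
    """A run parameter is missing or out of range."""


class DegenerateInputError(LTGError, ValueError):
    """The input is formally valid but carries no analyzable signal
    (e.g. a uniform recording, or a non-affected fold with zero
    vibrating area, for which the asymmetry ratio is undefined)."""
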
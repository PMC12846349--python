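"""Exception hierarchy shared across the toolkit."""


class CharkitError(Exception):
    """Base class for all toolkit errors."""


class EmptyInputError(CharkitError, ValueError):
    """Raised when an operation receives an empty file, list or sequence."""


class ParseError(CharkitError, ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


class UndefinedValueError(CharkitError, ArithmeticError):
    """Raised when a quantity is mathematically undefined for the input
    (e.g. GC content of an all-N sequence, identity of an all-gap pair)."""


class NoBurstError(CharkitError, ValueError):
    """Raised by one-step growth analysis when no rise above baseline is found."""


class UnterminatedRiseError(CharkitError, ValueError):
    """Raised by one-step growth analysis when a rise never reaches a plateau."""
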
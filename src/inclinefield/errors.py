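"""Exception hierarchy for inclinefield."""


class InclineFieldError(Exception):
    """Base class for all inclinefield errors."""


class ParseError(InclineFieldError):
    """A tracking file could not be parsed; the message names the line."""


class ValidationError(InclineFieldError):
    """Input data violated a contract (geometry, monotone time, coverage)."""


class EmptyHistogramError(InclineFieldError):
    """No directed steps survived the exclusions; no histogram exists."""


class DesignError(InclineFieldError):
    """An ANOVA design requirement (balance, completeness) was violated."""
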
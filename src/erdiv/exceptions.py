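"""Exception hierarchy for erdiv."""


class ErdivError(Exception):
    """Base class for all erdiv errors."""


class InvalidInputError(ErdivError, ValueError):
    """Raised when input data violate a structural precondition
    (negative abundances, all-zero communities, ragged tables, ...)."""


class UndefinedResultError(ErdivError, ValueError):
    """Raised when a statistic is mathematically undefined for the input,
    e.g. evenness of a single-species community (a 0/0 form)."""
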
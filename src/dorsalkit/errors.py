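"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input record, table, or configuration violates its contract.

    The command-line layer maps this to exit code 1; any other exception maps
    to exit code 2.
    """


class NotEvaluableError(ValidationError):
    """Raised when a score cannot be computed (e.g. every item inconclusive)."""
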
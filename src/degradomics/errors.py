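"""Exception hierarchy shared across the package."""


class DegradomicsError(Exception):
    """Base class for all package errors."""


class FormatError(DegradomicsError):
    """A file does not conform to the documented dialect (missing column,
    malformed value). The message names the offending column or line."""


class ValidationError(DegradomicsError):
    """Parsed content violates a domain invariant (duplicate symbols,
    out-of-range values, inconsistent backgrounds)."""


class UnknownGeneError(DegradomicsError, KeyError):
    """A gene symbol was looked up that is not present in the catalog."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"gene symbol not in catalog: {symbol!r}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class ConfigurationError(DegradomicsError):
    """A run-time parameter is outside its legal range."""


class NotEvaluableError(DegradomicsError):
    """A gene has no informative tumor/normal pair and cannot be quantified."""
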
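"""Exception hierarchy shared across the package."""


class LBStockError(Exception):
    """Base class for all package errors."""


class ParameterError(LBStockError, ValueError):
    """A function argument or model parameter is outside its valid domain."""


class DataError(LBStockError, ValueError):
    """Input data are insufficient or degenerate for the requested analysis."""


class FormatError(LBStockError, ValueError):
    """A file or table does not conform to the documented interchange format."""


class ConvergenceWarning(UserWarning):
    """An iterative fit finished but its diagnostics are below the quality floor."""
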
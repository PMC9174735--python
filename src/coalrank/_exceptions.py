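"""Exception hierarchy shared across the package."""


class CoalrankError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CoalrankError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DataError(CoalrankError, ValueError):
    """An input record violates a schema or consistency rule."""


class GenerationError(CoalrankError, RuntimeError):
    """The synthetic generator cannot satisfy its preconditions."""


class RatingLookupError(CoalrankError, KeyError):
    """A rating was requested outside a male's presence interval."""


class StandardizationError(CoalrankError, ValueError):
    """Min-max standardization is undefined (<2 males or zero range)."""


class CovariateError(CoalrankError, ValueError):
    """A covariate cannot be computed from the available data."""


class FittingError(CoalrankError, RuntimeError):
    """A model fit failed after all documented fallbacks."""


class BootstrapError(CoalrankError, RuntimeError):
    """Too many bootstrap refits failed to report a band."""


class UsageError(CoalrankError, ValueError):
    """An operation was called with incompatible arguments."""


class ValidationError(DataError):
    """Input validation failed; carries per-row diagnostics.

    Each diagnostic is a dict with keys ``file``, ``row`` and ``rule``.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = [f"{d.get('file', '?')}:{d.get('row', '?')}: {d.get('rule', '?')}"
                 for d in self.diagnostics[:20]]
        more = len(self.diagnostics) - len(lines)
        msg = "input validation failed:\n" + "\n".join(lines)
        if more > 0:
            msg += f"\n... and {more} more"
        super().__init__(msg)
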
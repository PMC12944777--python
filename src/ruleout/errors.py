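"""Exception hierarchy shared across the package."""


class RuleoutError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RuleoutError):
    """A parameter, column mapping, grid, or config file is invalid."""


class ValidationError(RuleoutError):
    """Input data violates a cohort invariant.

    Carries ``rows``: the 0-based row indices of offending records, when known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class InputError(RuleoutError):
    """An input is structurally unusable (missing file, empty cohort, absent labels)."""
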
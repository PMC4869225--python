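"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
ValidationError (and subclasses) -> 3, I/O problems -> 4.
"""


class AgendasetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AgendasetError):
    """Invalid parameter, threshold, or config file."""


class ValidationError(AgendasetError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A required column is missing or has the wrong shape."""


class RowError(ValidationError):
    """One or more rows failed field-level validation.

    ``problems`` is a list of (line_number, message) pairs; line numbers
    are 1-based and count the header row.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems)
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}")


class CoverageError(ValidationError):
    """Strict classification found accounts without a coded type."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} account(s) lack a coded type: "
            + ", ".join(self.missing_ids[:10])
            + ("..." if len(self.missing_ids) > 10 else "")
        )


class UndefinedMetricError(AgendasetError):
    """Metric is mathematically undefined for these inputs."""


class InconsistentInputError(ValidationError):
    """Inputs contradict each other (e.g. total exposure < impressions)."""
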
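"""Exception types shared across the pipeline stages."""


class ConfigError(ValueError):
    """An invalid parameter value (count < 1, fraction outside (0,1), ...)."""


class SchemaError(ValueError):
    """A table is missing a required column or contains malformed rows."""

    def __init__(self, message: str, column: str | None = None, line: int | None = None):
        super().__init__(message)
        self.column = column
        self.line = line


class InfeasibleMatchError(RuntimeError):
    """The background pool cannot supply the requested number of controls."""
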
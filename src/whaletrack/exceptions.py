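"""Exception hierarchy shared across the package."""


class WhaletrackError(Exception):
    """Base class for all package errors."""


class SchemaError(WhaletrackError):
    """Input table does not match the expected schema."""


class RowError(WhaletrackError):
    """A specific input row is unusable; carries the 1-based file line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ParameterError(WhaletrackError):
    """Invalid argument value."""


class ConfigurationError(WhaletrackError):
    """Missing or inconsistent configuration (e.g. an unknown Argos class)."""


class AnalysisError(WhaletrackError):
    """A downstream analysis cannot be performed on the given data."""
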
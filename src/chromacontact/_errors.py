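"""Exception hierarchy shared across the pipeline.

Configuration problems (bad column maps, unknown modes, invalid YAML) are
distinguished from data problems (malformed tables, impossible coordinates)
so the CLI can map them to distinct exit codes.
"""


class ChromacontactError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChromacontactError):
    """A config, dialect or mode is invalid. CLI exit code 2."""


class DataError(ChromacontactError):
    """Input data violates a precondition. CLI exit code 3."""
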
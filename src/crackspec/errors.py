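"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2,
MissingArtifactError -> 3, anything else -> 4.
"""


class CrackspecError(Exception):
    """Base class for package errors."""


class FormatError(CrackspecError, ValueError):
    """Malformed file contents or inconsistent container shapes."""


class ParameterError(CrackspecError, ValueError):
    """Invalid parameter value for an operation."""


class ConfigError(CrackspecError, ValueError):
    """Invalid or unknown run-configuration keys."""


class MissingArtifactError(CrackspecError, FileNotFoundError):
    """A pipeline stage needs an output another stage has not produced."""
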
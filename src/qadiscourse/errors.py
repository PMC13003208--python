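"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, SchemaError and
DataError -> 3, anything else -> 4.
"""


class QADiscourseError(Exception):
    """Base class for all package errors."""


class ConfigError(QADiscourseError):
    """Invalid or incomplete configuration (caught before any compute)."""


class SchemaError(QADiscourseError):
    """Input file violates the corpus record schema."""


class DataError(QADiscourseError):
    """Well-formed input that violates a pipeline precondition."""
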
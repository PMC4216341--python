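"""Exception hierarchy for the ethnokit pipeline."""


class EthnokitError(Exception):
    """Base class for all package errors."""


class SchemaError(EthnokitError):
    """An input table is missing a required column."""


class ValidationError(EthnokitError):
    """Input content violates the use-report data model."""


class DomainError(EthnokitError, ValueError):
    """A statistic was requested outside its mathematical domain."""
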
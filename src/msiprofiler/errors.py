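"""Exception hierarchy shared across the package."""


class MsiProfilerError(Exception):
    """Base class for all package errors."""


class FormatError(MsiProfilerError):
    """A tabular or VCF input violates the expected layout."""


class ValidationError(MsiProfilerError):
    """Parsed input violates a data-model invariant (e.g. duplicate rows)."""


class HgvsParseError(MsiProfilerError, ValueError):
    """An HGVS string could not be parsed; the message names the bad token."""


class ReferenceMismatchError(MsiProfilerError):
    """An HGVS-stated reference allele disagrees with the reference sequence."""


class ContractError(MsiProfilerError, TypeError):
    """An operation was called on input outside its contract."""


class EvaluationError(MsiProfilerError):
    """A cohort-level evaluation is impossible (e.g. an empty group)."""


class ConfigError(MsiProfilerError):
    """Pipeline or gene-set configuration is invalid."""
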
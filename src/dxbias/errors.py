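"""Exception hierarchy for dxbias.

All package errors derive from :class:`DxBiasError` so callers can catch one
base class; subclasses also inherit from the closest builtin (ValueError /
KeyError / LookupError) to stay idiomatic.
"""


class DxBiasError(Exception):
    """Base class for all dxbias errors."""


class KBValidationError(DxBiasError, ValueError):
    """A knowledge-base or case file violates its schema or invariants."""


class VocabularyError(DxBiasError, KeyError):
    """A finding or diagnosis label is not in the knowledge-base vocabulary."""


class LogParseError(DxBiasError, ValueError):
    """A session-log line could not be parsed; carries the line number."""


class LogIntegrityError(DxBiasError, ValueError):
    """A session log violates ordering/uniqueness invariants."""


class CaseLookupError(DxBiasError, LookupError):
    """A session references a case_id with no CaseDefinition."""


class PlanConstructionError(DxBiasError, ValueError):
    """The case library cannot satisfy the requested sequence design."""


class UndefinedScoreError(DxBiasError, ValueError):
    """A confidence bias score is requested for a case with no scoreable items."""
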
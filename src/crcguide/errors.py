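"""Exception hierarchy for the decision engine and evaluation harness."""


class CrcGuideError(Exception):
    """Base class for all package-level errors."""


class RulesetParseError(CrcGuideError):
    """The ruleset source does not conform to the documented schema.

    The message names the offending path within the document.
    """


class RulesetReferenceError(CrcGuideError):
    """A rule predicate references a variable not declared for its table."""


class EnumerationError(CrcGuideError):
    """A declared domain cannot be enumerated (e.g. an unbounded range)."""


class CoverageError(CrcGuideError):
    """No decision-table row matches the presented input point."""

    def __init__(self, message: str, point: dict | None = None):
        super().__init__(message)
        self.point = point or {}


class IntegrityError(CrcGuideError):
    """More than one decision-table row matches a single input point."""


class VocabularyError(CrcGuideError):
    """A code (condition or lesion feature) is absent from the declared vocabulary."""


class DomainError(CrcGuideError):
    """A scalar input lies outside its documented domain."""


class FormatError(CrcGuideError):
    """A response or answer record is malformed (wrong arity, unknown item)."""


class DegenerateDataError(CrcGuideError):
    """The data admit no informative statistic (constant sample, empty margin)."""


class DivergenceError(CrcGuideError):
    """An iterative calculation cannot reach its target (e.g. power at zero effect)."""
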
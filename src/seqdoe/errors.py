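"""Exception hierarchy.

Two branches matter for the CLI exit codes: ``ValidationError`` (bad inputs,
exit 2) and ``InfeasibleDesignError`` (no admissible design, exit 3).
"""


class SeqdoeError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqdoeError):
    """Invalid user input: malformed files, out-of-domain values, bad specs."""


class InvalidSpecError(ValidationError):
    """A design spec violates its invariants (e.g. non-positive level count)."""


class ParseError(ValidationError):
    """A file could not be parsed; carries row/column context in the message."""


class SchemaError(ValidationError):
    """A file parses but does not match the expected column layout."""


class ReferentialError(ValidationError):
    """A response row references a run_id absent from the companion design."""


class DomainError(ValidationError):
    """A numeric value is outside its domain (negative titre, p outside [0,1])."""


class UnknownFactorError(ValidationError, LookupError):
    """A factor name was requested that the design does not contain."""


class IncompleteSettingsError(ValidationError):
    """A prediction was requested without a level for every fitted factor."""


class InfeasibleDesignError(SeqdoeError):
    """No regular fraction with the requested resolution exists at this size."""


class InfeasibleAssignmentError(InfeasibleDesignError):
    """No factor-to-column assignment yields the required full projection."""


class BudgetExceededError(SeqdoeError):
    """Generator/word search exceeded its node budget (too many factors)."""


class NotRegularError(SeqdoeError):
    """A design is not a regular fraction, so word algebra does not apply."""


class EmptyDesignError(SeqdoeError):
    """Run removal left no surviving runs."""


class SingularModelError(SeqdoeError):
    """The model matrix is rank deficient; names the dependent columns."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class UndefinedMetricError(SeqdoeError):
    """R-squared is undefined (zero response variance)."""


class MismatchError(ValidationError):
    """Design and ground truth declare different factor sets."""


class InsufficientDataError(ValidationError):
    """Responses are missing for too large a share of the design's runs."""


class FewerSignificantFactorsError(SeqdoeError):
    """Fewer significant main effects than requested to fix; carries the count."""

    def __init__(self, available):
        super().__init__(
            f"only {available} significant main effects available to fix"
        )
        self.available = available


class EnumerationCapError(SeqdoeError):
    """Candidate-space enumeration would exceed the 2^20 cap."""


class IncompleteCellsError(SeqdoeError):
    """An interaction table has empty cells; lists the missing combinations."""

    def __init__(self, missing):
        super().__init__(f"empty interaction cells: {sorted(missing)}")
        self.missing = tuple(sorted(missing))
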
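"""Exception hierarchy shared across the package."""


class PPISelectError(Exception):
    """Base class for all ppiselect errors."""


class ValidationError(PPISelectError, ValueError):
    """A configuration or data object violates one of its invariants."""


class TableParseError(PPISelectError, ValueError):
    """A delimited feature-table file could not be parsed.

    Carries 1-based row/column coordinates of the offending cell when known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | int | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class UndefinedIdentityError(PPISelectError, ValueError):
    """Direction cosine requested for a zero feature vector."""


class StratificationError(PPISelectError, ValueError):
    """Stratified folds cannot be built (a class has fewer members than folds)."""


class NeighborError(PPISelectError, ValueError):
    """The minority class is too small for the requested neighbor count."""


class RuleResolutionError(PPISelectError, KeyError):
    """A rule references features absent from the table it is applied to."""


class RuleSyntaxError(PPISelectError, ValueError):
    """A rule-set text file violates the rule grammar."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
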
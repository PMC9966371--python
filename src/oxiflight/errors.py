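"""Exception hierarchy for oxiflight."""


class OxiflightError(Exception):
    """Base class for all oxiflight errors."""


class FormatError(OxiflightError):
    """A flight-record file violates the dialect.

    Carries the offending row (1-based, counting the header as row 0) and
    field name when they are known, so error messages can point at the
    exact cell.
    """

    def __init__(self, message: str, *, row: int | None = None,
                 field: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field is not None:
            loc.append(f"field '{field}'")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.field = field


class ContractError(OxiflightError):
    """An operation was called on data violating its preconditions
    (e.g. misaligned channels)."""


class InsufficientDataError(OxiflightError):
    """Too few non-missing samples for the requested computation."""


class FilterSpecError(OxiflightError):
    """A cohort filter specification is malformed or inconsistent."""


class EmptyCohortError(OxiflightError):
    """A filter removed every subject from the sample."""
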
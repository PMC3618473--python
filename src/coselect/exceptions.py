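"""Exception types shared across the package."""


class CoselectError(Exception):
    """Base class for package errors."""


class TableFormatError(CoselectError):
    """A required column is missing or a table is structurally invalid."""


class RowParseError(CoselectError):
    """A row holds an unparseable value; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UntestableError(CoselectError):
    """A contingency configuration admits no test (e.g. expected count 0)."""


class InfeasibleCouplingError(CoselectError):
    """A planted pairwise coupling is incompatible with its marginals."""
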
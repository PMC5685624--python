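"""Exception hierarchy."""


class SSRPopError(Exception):
    """Base class for all ssrpop errors."""


class FormatError(SSRPopError):
    """Structurally invalid input file (duplicate ids, missing columns...)."""


class ParseError(SSRPopError):
    """A cell or token could not be interpreted; carries coordinates."""

    def __init__(self, message: str, row: int | None = None, column: str | int | None = None):
        if row is not None or column is not None:
            message = f"{message} (row={row}, column={column})"
        super().__init__(message)
        self.row = row
        self.column = column


class ParameterError(SSRPopError):
    """An argument is outside its documented domain."""


class DataError(SSRPopError):
    """Data violate a precondition of an analysis (degenerate group, no shared loci...)."""
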
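"""Package-level exception types."""

from .chem import UnsupportedPeptideError  # re-export  # noqa: F401


class MGFParseError(ValueError):
    """A malformed MGF block; the message names the offending block index."""


class MissingColumnError(KeyError):
    """A required column is absent from a search-engine table."""

    def __init__(self, column: str, table: str):
        super().__init__(column)
        self.column = column
        self.table = table

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"required column {self.column!r} missing from {self.table}"


class CalibrationError(RuntimeError):
    """Collision-energy calibration could not be performed."""


class RescoringError(RuntimeError):
    """Rescoring engine failure (e.g. missing external binary)."""


class LeakGuardError(RuntimeError):
    """A calibration model was fitted on peptides outside the training split."""
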
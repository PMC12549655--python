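"""Structured exceptions raised across the pipeline."""

from __future__ import annotations


class GmimmuneError(Exception):
    """Base class for all pipeline errors."""


class MissingProfileCellError(GmimmuneError):
    """An effect profile does not cover a (gene, treatment, time) cell."""

    def __init__(self, gene: str, treatment: str, time_h: float):
        self.cell = (gene, treatment, time_h)
        super().__init__(
            f"no fold-change profile for gene={gene!r}, treatment={treatment!r}, "
            f"time_h={time_h!r}"
        )


class InvalidCategoryError(GmimmuneError):
    """A health observation carries a value outside its rubric levels."""

    def __init__(self, field: str, value):
        self.field = field
        self.value = value
        super().__init__(f"invalid level {value!r} for health category {field!r}")


class QpcrError(GmimmuneError):
    """Relative-expression computation cannot proceed."""


class MissingHousekeepingError(QpcrError):
    def __init__(self, treatment: str, time_h: float, bio_rep):
        super().__init__(
            f"housekeeping Ct missing for treatment={treatment!r}, "
            f"time_h={time_h!r}, bio_rep={bio_rep!r}"
        )


class MissingControlError(QpcrError):
    def __init__(self, gene: str, time_h: float):
        super().__init__(
            f"no control-group Ct for gene={gene!r} at time_h={time_h!r}; "
            "a time-matched control baseline is required"
        )


class PairingError(GmimmuneError):
    """Cross-treatment correlation requires a matched replicate structure."""

    def __init__(self, unmatched):
        self.unmatched = list(unmatched)
        super().__init__(f"unmatched (time_h, bio_rep) cells: {self.unmatched}")


class AlignmentFormatError(GmimmuneError):
    """An aligned pair violates the two-record, equal-length, legal-alphabet contract."""
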
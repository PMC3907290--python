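"""Exception hierarchy shared across the package."""


class SplicebindError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SplicebindError):
    """Malformed input file (FASTA/BED/TSV)."""


class AlphabetError(SplicebindError):
    """A residue outside {A, C, G, U/T} was encountered."""

    def __init__(self, record_id: str, position: int, residue: str):
        self.record_id = record_id
        self.position = position  # 1-based, for humans
        self.residue = residue
        super().__init__(
            f"record {record_id!r}: invalid residue {residue!r} at position {position}"
        )


class CoordinateError(SplicebindError):
    """Interval coordinates violate 0 <= start < end or fall off the chromosome."""


class LookupError_(SplicebindError):
    """A chromosome or record id is missing from the provided mapping."""


class TooShortError(SplicebindError):
    """Sequence too short for the requested operation (e.g. < 3 nt for triplets)."""


class DegenerateInputError(SplicebindError):
    """Statistically degenerate input: zero variance, empty null, constant vector."""


class NumericalError(SplicebindError):
    """Non-finite likelihood or other numerical failure during model fitting."""
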
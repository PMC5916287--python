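"""Core data model shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; SAM's
1-based POS is converted at the format boundary (see :mod:`circinfer.seqio`).

Alignment columns are stored as an expanded per-column operation string over

* ``M`` — match (read base equals reference base),
* ``X`` — mismatch (both consume, bases differ),
* ``I`` — insertion (read base with no reference base),
* ``D`` — deletion (reference base with no read base).

Soft-clipped bases from external SAM files are dropped on ingestion; they
consume neither coverage nor connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NORMALIZE = {c: c for c in "ACGTN"}


def normalize_sequence(seq: str) -> str:
    """Uppercase a DNA string and map any symbol outside {A,C,G,T,N} to N."""
    up = seq.upper()
    if all(c in _NORMALIZE for c in up):
        return up
    return "".join(c if c in _NORMALIZE else "N" for c in up)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named DNA sequence with optional Phred qualities.

    ``sequence`` is normalized (uppercase, non-ACGTN mapped to N);
    ``qualities``, when present, has one integer per base.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadAlignment:
    """One read's end-to-end alignment against a single reference.

    ``columns`` is the expanded M/X/I/D operation string (empty when
    unmapped), always in reference orientation; for a read mapped to the
    reverse strand (``strand == "-"``) the columns describe the reverse
    complement of the read.  ``score`` is 0 for a perfect alignment and
    negative otherwise; for unmapped reads it records the best score
    found before the floor was applied.
    """

    read_id: str
    ref_start: int
    ref_end: int
    columns: str
    score: int
    mapped: bool = True
    strand: str = "+"
    note: str = ""

    def __post_init__(self) -> None:
        if self.mapped:
            ref_len = sum(1 for c in self.columns if c in "MXD")
            if ref_len != self.ref_end - self.ref_start:
                raise FormatError(
                    f"alignment {self.read_id!r}: columns consume {ref_len} "
                    f"reference bases but interval is "
                    f"[{self.ref_start},{self.ref_end})"
                )

    @property
    def read_length(self) -> int:
        """Read bases consumed by the alignment columns."""
        return sum(1 for c in self.columns if c in "MXI")

    @property
    def n_gap_columns(self) -> int:
        return sum(1 for c in self.columns if c in "ID")


@dataclass
class PositionProfile:
    """Per-position coverage and connectivity along a reference."""

    length: int
    coverage: "list[int] | object" = field(repr=False)  # numpy array in practice
    connectivity: "list[int] | object" = field(repr=False)
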
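"""Core peptide type over the 20 canonical amino acids.

Positions are 1-based throughout the package and the initiator methionine of
an ORF is position 1, so "the +2 position" of a targeting peptide means the
residue at sequence index 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

#: The 20 canonical one-letter residue codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the canonical 20-letter alphabet."""

    def __init__(self, peptide_id: str, position: int, residue: str):
        self.peptide_id = peptide_id
        self.position = position
        self.residue = residue
        super().__init__(
            f"peptide {peptide_id!r}: invalid residue {residue!r} at position "
            f"{position} (ambiguity codes B/Z/X/U/O are rejected)"
        )


@dataclass(frozen=True)
class Peptide:
    """An identified amino-acid sequence.

    The sequence is folded to upper case on construction and validated against
    the canonical alphabet; empty sequences and ambiguity codes are rejected.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        for i, aa in enumerate(seq, start=1):
            if aa not in _AA_SET:
                raise InvalidResidueError(self.id, i, aa)

    def __len__(self) -> int:
        return len(self.seq)

    def __iter__(self) -> Iterator[str]:
        return iter(self.seq)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.seq):
            raise IndexError(
                f"position {position} outside 1..{len(self.seq)} for {self.id!r}"
            )
        return self.seq[position - 1]

    def subsequence(self, start: int, end: int, id: str | None = None) -> "Peptide":
        """1-based inclusive subsequence [start, end]."""
        if not (1 <= start <= end <= len(self.seq)):
            raise IndexError(
                f"range {start}..{end} outside 1..{len(self.seq)} for {self.id!r}"
            )
        return Peptide(id or f"{self.id}_{start}-{end}", self.seq[start - 1 : end])

    def count(self, residues: str) -> int:
        """Number of positions holding any of the given residues."""
        rs = set(residues)
        return sum(1 for aa in self.seq if aa in rs)


def as_peptide(obj: "Peptide | str", id: str = "peptide") -> Peptide:
    """Coerce a raw string (validated) or pass through a Peptide."""
    if isinstance(obj, Peptide):
        return obj
    return Peptide(id, obj)
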
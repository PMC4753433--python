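"""Protein/peptide bookkeeping for HDX-MS: observable amides and coverage.

Coordinates are 1-based inclusive throughout, matching the residue numbering
used in HDX reports; conversion to half-open slices happens only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProteinSequence", "Peptide", "observable_amides", "coverage_fraction"]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter amino-acid string, 1-based numbering ('X' = unknown)."""

    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _AA
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Substring for the 1-based inclusive span [start, end]."""
        if not 1 <= start <= end <= len(self.residues):
            raise ValueError(f"span {start}-{end} outside 1..{len(self.residues)}")
        return self.residues[start - 1:end]


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment with 1-based inclusive coordinates."""

    id: str
    start: int
    end: int
    sequence: str
    charge: int = 1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @classmethod
    def from_protein(cls, seq: ProteinSequence, start: int, end: int,
                     charge: int = 1, id: str | None = None) -> "Peptide":
        pid = id if id is not None else f"{start}-{end}"
        return cls(pid, start, end, seq.slice(start, end), charge)

    def validate_against(self, seq: ProteinSequence) -> None:
        if self.sequence != seq.slice(self.start, self.end):
            raise ValueError(
                f"peptide {self.id} sequence does not match protein "
                f"residues {self.start}-{self.end}")


def observable_amides(p: Peptide, seq: ProteinSequence,
                      n_term_loss: int = 1) -> list[int]:
    """Residue positions carrying measurable backbone amides.

    The peptide's first ``n_term_loss`` residue(s) (fast back-exchange at the
    new N-terminus) and every proline (no amide hydrogen) are excluded.  The
    one-residue loss is the default convention; a two-residue variant is
    available via ``n_term_loss=2``.
    """
    p.validate_against(seq)
    if n_term_loss < 1:
        raise ValueError("n_term_loss must be >= 1")
    return [i for i in range(p.start + n_term_loss, p.end + 1)
            if seq[i] != "P"]


def coverage_fraction(peptides: list[Peptide], seq: ProteinSequence) -> float:
    """Percent of protein residues inside the union of peptide spans."""
    covered: set[int] = set()
    for p in peptides:
        p.validate_against(seq)
        covered.update(range(p.start, p.end + 1))
    return 100.0 * len(covered) / len(seq)
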
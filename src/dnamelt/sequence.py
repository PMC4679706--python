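"""DNA sequences: parsing, Watson-Crick complementation and FASTA I/O.

A :class:`Sequence` is the 5'→3' base string of one strand; under the
perfect-matching assumption it fully determines the duplex, the second
strand being its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

VALID_BASES = "ACGT"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class Sequence:
    """One DNA strand, read 5'→3', restricted to the A/C/G/T alphabet."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("sequence must contain at least one base")
        for i, b in enumerate(self.bases, start=1):
            if b not in VALID_BASES:
                raise ValueError(
                    f"invalid symbol {b!r} at position {i}: only A, C, G, T allowed"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self):
        return iter(self.bases)

    def __getitem__(self, i):
        return self.bases[i]

    @property
    def at_fraction(self) -> float:
        """Fraction of A or T bases."""
        return sum(b in "AT" for b in self.bases) / len(self.bases)


def parse_sequence(text: str, name: str = "") -> Sequence:
    """Parse a raw base string, tolerating whitespace grouping and case.

    Raises ``ValueError`` naming the (1-based) offending position if a symbol
    outside A/C/G/T is present.
    """
    stripped = "".join(text.split()).upper()
    if not stripped:
        raise ValueError("empty sequence")
    return Sequence(stripped, name=name)


def complement(seq: Sequence) -> Sequence:
    """Watson-Crick complementary strand, itself read 5'→3'.

    This is the reverse complement of the input string: the partner strand
    runs antiparallel, so reading it 5'→3' reverses the base order.
    """
    comp = "".join(_WC[b] for b in reversed(seq.bases))
    return Sequence(comp, name=f"{seq.name}_complement" if seq.name else "")


def read_fasta(path: str | Path) -> List[Sequence]:
    """Read one or more sequences from a FASTA file (description kept as name)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [parse_sequence(str(r.seq), name=r.description) for r in records]


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(_BioSeq(s.bases), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(seqs, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")
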
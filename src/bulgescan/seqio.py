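"""Sequence and table I/O.

All sequences are normalized to the RNA alphabet {A, C, G, U} on input
(uppercased, T -> U); IUPAC ambiguity codes are rejected.  Transcript
coordinates are 1-based and inclusive on the sense strand throughout the
package; miRNA positions are 1-based from the miRNA 5' end, matching the
community convention that slicing occurs opposite miRNA nucleotides 10/11.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified RNA sequence over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGU characters after "
                f"normalization: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def normalize(residues: str) -> str:
    """Uppercase and convert DNA T to RNA U (no validation)."""
    return residues.upper().replace("T", "U")


def make_sequence(seq_id: str, residues: str) -> NucleotideSequence:
    """Build a NucleotideSequence from raw (possibly DNA, mixed-case) text."""
    return NucleotideSequence(id=seq_id, residues=normalize(residues))


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """RNA reverse complement (A<->U, C<->G); an involution."""
    return NucleotideSequence(id=s.id, residues=s.residues.translate(_COMPLEMENT)[::-1])


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into normalized RNA sequences.

    DNA input is silently converted (T -> U) and case is folded to upper.
    Raises ValueError for an empty file or for any record containing IUPAC
    ambiguity codes, naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        try:
            out.append(make_sequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(str(exc)) from None
    return out


def read_fastq(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTQ reads (qualities discarded) into normalized RNA sequences."""
    records = list(SeqIO.parse(str(path), "fastq"))
    if not records:
        raise ValueError(f"no FASTQ records found in {path}")
    return [make_sequence(rec.id, str(rec.seq)) for rec in records]


def read_reads(path: str | Path) -> list[NucleotideSequence]:
    """Read degradome reads from FASTA or FASTQ, sniffing the format."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s), width):
                fh.write(s.residues[i : i + width] + "\n")


def write_fastq(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f"@{s.id}\n{s.residues}\n+\n{'I' * len(s)}\n")
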
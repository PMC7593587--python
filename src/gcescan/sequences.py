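"""Sequence containers and FASTA/FASTQ ingest.

Nucleotide sequences are stored uppercase over the alphabet ``{A,C,G,T,N}``;
RNA input (``U``) is accepted and mapped to ``T`` on ingest.  Protein
sequences use one-letter symbols: the 20 canonical residues plus ``O``
(pyrrolysine), ``U`` (selenocysteine) and ``X`` (residue from an ambiguous
codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gcescan.sequences")

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYOUX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside its alphabet."""


def _normalize_dna(raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise SequenceAlphabetError(
                f"non-IUPAC nucleotide {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence, uppercased and validated on construction."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalize_dna(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein in one-letter code; ``O``/``U`` mark recoded residues.

    ``source_gene`` optionally points back to the :class:`~gcescan.orfs.GeneCall`
    the protein was translated from.
    """

    id: str
    seq: str
    description: str = ""
    source_gene: Optional[object] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        bad = set(self.seq) - PROTEIN_ALPHABET - {"*"}
        if bad:
            raise SequenceAlphabetError(
                f"unexpected residue symbols {sorted(bad)} in protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Applying it twice returns a sequence equal to the input (involution).
    """
    return NucleotideSequence(
        id=s.id, seq=s.seq.translate(_COMPLEMENT)[::-1], description=s.description
    )


def revcomp_str(seq: str) -> str:
    """Reverse complement of a plain (already validated) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ round-trips (Biopython-backed; FASTA wrapped at 60 columns)

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            NucleotideSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def read_fastq(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTQ; quality strings are ignored downstream."""
    return [
        NucleotideSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_transcripts(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTA or FASTQ based on the leading record character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def _to_seqrecords(seqs: Iterable[NucleotideSequence | ProteinSequence]):
    for s in seqs:
        yield SeqRecord(Seq(s.seq), id=s.id, description=s.description)


def write_fasta(seqs: Iterable[NucleotideSequence | ProteinSequence],
                path: str | Path) -> None:
    SeqIO.write(_to_seqrecords(seqs), str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
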
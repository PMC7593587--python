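"""Deterministic ORF scanning under a configurable genetic code.

This is a purposely simple maximal-ORF scanner: a gene begins at a start
codon, runs to the first in-frame terminator of the active table, and within
each (strand, frame, terminator) group only the longest ORF (earliest start)
is kept.  Coordinates are 0-based half-open on the forward strand throughout;
``end`` includes the terminator when one was found.  ORFs that run off the
contig end are emitted with the 3' partial flag set and no terminator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .codes import GeneticCodeTable
from .sequences import NucleotideSequence, ProteinSequence, revcomp_str

DEFAULT_MIN_AA = 50


@dataclass(frozen=True)
class GeneCall:
    """A predicted coding region with strand-aware genomic coordinates."""

    contig_id: str
    start: int          # 0-based, forward strand
    end: int            # half-open, forward strand
    strand: str         # '+' or '-'
    table_name: str
    protein: ProteinSequence
    partial_5prime: bool = False
    partial_3prime: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if (self.end - self.start) % 3:
            raise ValueError("gene span must be divisible by 3")

    @property
    def has_terminator(self) -> bool:
        return not self.partial_3prime

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    def codon_interval(self, codon_index: int) -> tuple[int, int]:
        """Forward-strand interval of the given in-gene codon (strand-aware)."""
        if self.strand == "+":
            a = self.start + 3 * codon_index
        else:
            a = self.end - 3 * (codon_index + 1)
        return a, a + 3

    def codon_at(self, contig: NucleotideSequence, codon_index: int) -> str:
        """The codon as read in the gene's reading direction."""
        a, b = self.codon_interval(codon_index)
        codon = contig.seq[a:b]
        return codon if self.strand == "+" else revcomp_str(codon)


def _translate_codons(codons: list[str], table: GeneticCodeTable) -> str:
    # gene-context translation: first codon is the start codon -> Met
    out = ["M"]
    for codon in codons[1:]:
        out.append(table.residue(codon))
    return "".join(out)


def _scan_strand(ss: str, contig_id: str, strand: str, total_len: int,
                 table: GeneticCodeTable, min_aa: int) -> list[GeneCall]:
    calls: list[GeneCall] = []
    n = len(ss)
    for offset in range(3):
        codons = [ss[i:i + 3] for i in range(offset, n - 2, 3)]
        seg_start = 0  # codon index where the current stop-to-stop segment begins
        for ci, codon in enumerate(codons):
            if not table.is_stop(codon):
                continue
            call = _segment_call(codons, seg_start, ci, offset, ss, contig_id,
                                 strand, total_len, table, min_aa,
                                 terminated=True)
            if call is not None:
                calls.append(call)
            seg_start = ci + 1
        # trailing segment: runs off the contig end
        if seg_start < len(codons):
            call = _segment_call(codons, seg_start, len(codons), offset, ss,
                                 contig_id, strand, total_len, table, min_aa,
                                 terminated=False)
            if call is not None:
                calls.append(call)
    return calls


def _segment_call(codons, seg_start, seg_stop, offset, ss, contig_id, strand,
                  total_len, table, min_aa, terminated) -> Optional[GeneCall]:
    """Longest ORF in one stop-to-stop segment (first start codon wins)."""
    for ci in range(seg_start, seg_stop):
        if codons[ci] in table.starts:
            n_res = seg_stop - ci
            if n_res < min_aa:
                return None
            s_local = offset + 3 * ci
            e_local = offset + 3 * (seg_stop + (1 if terminated else 0))
            protein = ProteinSequence(
                id=f"{contig_id}|{strand}{s_local}",
                seq=_translate_codons(codons[ci:seg_stop], table),
            )
            if strand == "+":
                start, end = s_local, e_local
            else:
                start, end = total_len - e_local, total_len - s_local
            return GeneCall(
                contig_id=contig_id, start=start, end=end, strand=strand,
                table_name=table.name, protein=protein,
                partial_3prime=not terminated,
            )
    return None


def find_orfs(contig: NucleotideSequence, table: GeneticCodeTable,
              min_aa: int = DEFAULT_MIN_AA) -> list[GeneCall]:
    """All maximal ORFs on both strands with at least ``min_aa`` residues.

    Returns calls sorted by (start, end, strand).  A contig too short to hold
    any qualifying ORF yields an empty list.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if len(contig.seq) < 3 * (min_aa + 1):
        return []
    calls = _scan_strand(contig.seq, contig.id, "+", len(contig.seq), table, min_aa)
    calls += _scan_strand(revcomp_str(contig.seq), contig.id, "-",
                          len(contig.seq), table, min_aa)
    calls.sort(key=lambda g: (g.start, g.end, g.strand))
    return calls
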
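"""Second-pass gene extension through repurposed stop codons.

For every first-pass gene terminated by the active readthrough codon
(TAG for pyrrolysine, TGA for selenocysteine) the gene is extended through
up to ``max_events`` such codons to the next hard stop, the consumed codon
is recorded as a :class:`RecodingEvent`, and the first-pass calls fused by
the extension are linked.  Whether a candidate is *reported* as recoded is
decided downstream by conservation scoring (see :mod:`gcescan.pathway`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .codes import GeneticCodeTable
from .orfs import GeneCall
from .sequences import NucleotideSequence, ProteinSequence, revcomp_str


@dataclass
class RecodingEvent:
    """An in-frame repurposed stop inside an extended gene."""

    gene: GeneCall                  # the extended (readthrough) gene
    codon: str                      # TAG or TGA
    codon_index: int                # 0-based codon position within the gene
    inserted_residue: str           # 'O' or 'U'
    upstream_gene: Optional[GeneCall] = None
    downstream_gene: Optional[GeneCall] = None
    conservation: Optional[object] = None  # ConservationReport, set later

    def __post_init__(self) -> None:
        if self.gene.protein.seq[self.codon_index] != self.inserted_residue:
            raise ValueError(
                "extended protein does not carry the inserted residue at the "
                f"event codon index {self.codon_index}"
            )


def requires_readthrough_pass(inventory) -> bool:
    """True iff the pyrrolysine biosynthesis enzymes (pylB, pylC, pylD) are
    all present in the genome's pathway inventory."""
    rows = getattr(inventory, "rows", inventory)
    if not rows:
        return False
    return all(
        key in rows and rows[key].status == "present"
        for key in ("pylB", "pylC", "pylD")
    )


def _strand_coords(gene: GeneCall, total_len: int) -> tuple[int, int]:
    """Gene interval in reading-strand coordinates."""
    if gene.strand == "+":
        return gene.start, gene.end
    return total_len - gene.end, total_len - gene.start


def find_readthrough_candidates(
    contig: NucleotideSequence,
    first_pass: list[GeneCall],
    rt_table: GeneticCodeTable,
    max_events: int = 1,
) -> list[RecodingEvent]:
    """Extend amber/opal-terminated first-pass genes through the readthrough
    codon of ``rt_table``.

    One :class:`RecodingEvent` is emitted per consumed codon; with the default
    ``max_events=1`` each candidate gene consumes exactly one repurposed stop.
    Extension past ``max_events`` readthrough codons stops at the next such
    codon, which is then treated as the terminator.  Candidates whose extended
    span is fully contained in another candidate on the same strand are
    dropped.  An extension that runs off the contig is kept with the 3'
    partial flag.
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    if len(rt_table.readthrough) != 1:
        raise ValueError("rt_table must define exactly one readthrough codon")
    rt_codon, rt_residue = next(iter(rt_table.readthrough.items()))

    total = len(contig.seq)
    events: list[RecodingEvent] = []
    for gene in first_pass:
        if gene.partial_3prime:
            continue
        if gene.codon_at(contig, gene.n_codons - 1) != rt_codon:
            continue
        events.extend(
            _extend_gene(contig, gene, first_pass, rt_table, rt_codon,
                         rt_residue, max_events, total)
        )
    return _drop_contained(events)


def _extend_gene(contig, gene, first_pass, rt_table, rt_codon, rt_residue,
                 max_events, total) -> list[RecodingEvent]:
    ss = contig.seq if gene.strand == "+" else revcomp_str(contig.seq)
    s_local, e_local = _strand_coords(gene, total)
    # walk codons beyond the consumed terminator
    consumed = [gene.n_codons - 1]          # codon indices of readthrough codons
    pos = e_local                            # reading-strand position after gene
    terminated = True
    while True:
        codon = ss[pos:pos + 3]
        if len(codon) < 3:
            terminated = False
            break
        ci = (pos - s_local) // 3
        if codon == rt_codon:
            if len(consumed) >= max_events:
                pos += 3  # excess readthrough codon acts as the terminator
                break
            consumed.append(ci)
        elif rt_table.is_stop(codon):
            pos += 3
            break
        pos += 3
    e_ext_local = pos if terminated else s_local + 3 * ((pos - s_local) // 3)
    region = ss[s_local:e_ext_local]
    n_cod = len(region) // 3
    n_res = n_cod - (1 if terminated else 0)
    residues = ["M"]
    for k in range(1, n_res):
        residues.append(rt_table.residue(region[3 * k: 3 * k + 3]))
    protein = ProteinSequence(
        id=f"{gene.protein.id}|rt", seq="".join(residues))
    if gene.strand == "+":
        start, end = s_local, s_local + 3 * n_cod
    else:
        start, end = total - (s_local + 3 * n_cod), total - s_local
    extended = GeneCall(
        contig_id=gene.contig_id, start=start, end=end, strand=gene.strand,
        table_name=rt_table.name, protein=protein,
        partial_3prime=not terminated,
    )
    downstream = _find_downstream(extended, gene, first_pass)
    return [
        RecodingEvent(
            gene=extended, codon=rt_codon, codon_index=ci,
            inserted_residue=rt_residue, upstream_gene=gene,
            downstream_gene=downstream,
        )
        for ci in consumed
    ]


def _find_downstream(extended: GeneCall, upstream: GeneCall,
                     first_pass: list[GeneCall]) -> Optional[GeneCall]:
    """First-pass call fused at the 3' side: same strand/terminator as the
    extended gene, starting inside the extension."""
    for g in first_pass:
        if g is upstream or g.strand != extended.strand:
            continue
        if g.contig_id != extended.contig_id or g.partial_3prime != extended.partial_3prime:
            continue
        if extended.strand == "+":
            if g.end == extended.end and g.start > upstream.start:
                return g
        else:
            if g.start == extended.start and g.end < upstream.end:
                return g
    return None


def _drop_contained(events: list[RecodingEvent]) -> list[RecodingEvent]:
    out = []
    for ev in events:
        g = ev.gene
        contained = any(
            o is not ev
            and o.gene.strand == g.strand
            and o.gene.contig_id == g.contig_id
            and o.gene.start <= g.start
            and g.end <= o.gene.end
            and (o.gene.start, o.gene.end) != (g.start, g.end)
            for o in events
        )
        if not contained:
            out.append(ev)
    return out
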
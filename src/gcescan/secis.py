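"""Bacterial SECIS-like stem-loop search downstream of in-frame TGA codons.

A paired-base-maximizing hairpin search (G-T wobble allowed) stands in for a
full free-energy model: for each in-frame TGA of a readthrough gene the
coding strand is searched up to ``max_offset`` nt downstream of the codon
for the longest fully paired stem with a 3-12 nt loop, and the best hairpin
per TGA is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orfs import GeneCall
from .sequences import NucleotideSequence, revcomp_str

MIN_STEM = 7
MAX_OFFSET = 15
MAX_STEM = 20
LOOP_RANGE = range(3, 13)

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class SecisHit:
    contig_id: str
    tga_codon_index: int     # codon index of the TGA within the gene
    tga_pos: int             # forward-strand start of the TGA codon
    offset_nt: int           # distance from TGA 3' end to stem start
    stem_len: int            # fully paired stem length
    loop_len: int
    score: int               # paired bases (== stem_len for a full stem)


def _best_hairpin(region: str, min_stem: int, max_offset: int):
    """(offset, stem, loop) maximizing stem length; ties prefer smaller
    offset, then smaller loop.  The stem must be fully paired."""
    best = None
    for offset in range(0, max_offset + 1):
        for stem in range(min_stem, MAX_STEM + 1):
            for loop in LOOP_RANGE:
                end = offset + 2 * stem + loop
                if end > len(region):
                    break
                s5 = region[offset: offset + stem]
                s3 = region[offset + stem + loop: end]
                if all((s5[k], s3[stem - 1 - k]) in _PAIRS for k in range(stem)):
                    cand = (stem, -offset, -loop)
                    if best is None or cand > best[:3]:
                        best = (stem, -offset, -loop, offset, loop)
    return best


def scan_secis(gene: GeneCall, contig: NucleotideSequence,
               min_stem: int = MIN_STEM,
               max_offset: int = MAX_OFFSET) -> list[SecisHit]:
    """Best SECIS-like hairpin downstream of each in-frame TGA in ``gene``.

    The gene must carry at least one in-frame TGA (i.e. it was called under
    TGA readthrough); the search runs on the coding strand, inside and
    past the codon, limited to ``max_offset`` nt of offset.
    """
    ss = contig.seq if gene.strand == "+" else revcomp_str(contig.seq)
    if gene.strand == "+":
        s_local = gene.start
    else:
        s_local = len(contig.seq) - gene.end
    tga_indices = [
        ci for ci in range(gene.n_codons)
        if ss[s_local + 3 * ci: s_local + 3 * ci + 3] == "TGA"
        and ci < gene.n_codons - (0 if gene.partial_3prime else 1)
    ]
    if not tga_indices:
        raise ValueError(f"gene at {gene.start}-{gene.end} has no in-frame TGA")
    hits = []
    for ci in tga_indices:
        after = s_local + 3 * ci + 3
        region = ss[after: after + max_offset + 2 * MAX_STEM + max(LOOP_RANGE) + 1]
        found = _best_hairpin(region, min_stem, max_offset)
        if found is None:
            continue
        stem, _, _, offset, loop = found
        tga_fwd = gene.codon_interval(ci)[0]
        hits.append(SecisHit(
            contig_id=gene.contig_id, tga_codon_index=ci, tga_pos=tga_fwd,
            offset_nt=offset, stem_len=stem, loop_len=loop, score=stem))
    return hits
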
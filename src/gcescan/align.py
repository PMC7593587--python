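"""Affine-gap pairwise protein alignment.

Backed by Biopython's ``PairwiseAligner`` with a BLOSUM62 matrix extended to
the noncanonical residues ``O`` (pyrrolysine) and ``U`` (selenocysteine):
both score positively only against themselves and as ordinary mismatches
against everything else.  Gap costs follow the convention that the first gap
position costs the open score and each subsequent position the extend score
(so a gap of length L costs 11 + (L-1) with the defaults).

Percent identity is computed over aligned columns excluding end gaps;
coverage is the aligned reference span relative to the reference length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import ProteinSequence

GAP_OPEN = -11.0
GAP_EXTEND = -1.0
SELF_MATCH_OU = 6.0
MISMATCH_OU = -4.0

Mode = Literal["global", "local"]


@lru_cache(maxsize=None)
def extended_blosum62() -> substitution_matrices.Array:
    """BLOSUM62 with O and U appended to the alphabet."""
    base = substitution_matrices.load("BLOSUM62")
    alphabet = str(base.alphabet).replace("*", "") + "OU"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a in "OU" or b in "OU":
                mat[a, b] = SELF_MATCH_OU if a == b else MISMATCH_OU
            else:
                mat[a, b] = base[a, b]
    return mat


@lru_cache(maxsize=None)
def _aligner(mode: Mode, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = extended_blosum62()
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal pairwise alignment of a query against a reference."""

    mode: str
    score: float
    identity_pct: float     # matches / aligned columns excluding end gaps
    coverage_pct: float     # aligned reference span / reference length
    matches: int
    aligned_columns: int
    query_span: tuple[int, int]  # half-open on the query
    ref_span: tuple[int, int]    # half-open on the reference


def align_proteins(a: ProteinSequence | str, b: ProteinSequence | str,
                   mode: Mode = "global",
                   open_gap: float = GAP_OPEN,
                   extend_gap: float = GAP_EXTEND) -> AlignmentResult:
    """Align query ``a`` against reference ``b``; returns the DP optimum."""
    qa = a.seq if isinstance(a, ProteinSequence) else a
    rb = b.seq if isinstance(b, ProteinSequence) else b
    if not qa or not rb:
        raise ValueError("cannot align an empty protein sequence")
    aligner = _aligner(mode, open_gap, extend_gap)
    aln = aligner.align(qa, rb)[0]
    q_blocks, r_blocks = aln.aligned
    if len(q_blocks) == 0:  # local alignment of fully dissimilar sequences
        return AlignmentResult(mode=mode, score=aln.score, identity_pct=0.0,
                               coverage_pct=0.0, matches=0, aligned_columns=0,
                               query_span=(0, 0), ref_span=(0, 0))
    matches = 0
    block_len = 0
    for (qs, qe), (rs, re) in zip(q_blocks.tolist(), r_blocks.tolist()):
        block_len += qe - qs
        matches += sum(qa[qs + k] == rb[rs + k] for k in range(qe - qs))
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    r0, r1 = int(r_blocks[0][0]), int(r_blocks[-1][1])
    columns = (q1 - q0) + (r1 - r0) - block_len
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (r1 - r0) / len(rb)
    identity, coverage = float(identity), float(coverage)
    return AlignmentResult(mode=mode, score=float(aln.score),
                           identity_pct=identity, coverage_pct=coverage,
                           matches=matches, aligned_columns=columns,
                           query_span=(q0, q1), ref_span=(r0, r1))
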
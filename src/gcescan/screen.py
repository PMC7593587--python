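"""Translated homology screen of transcripts against the pathway proteins.

Each transcript is six-frame translated — readthrough-aware for genes that
expect it (TAG->O for pyrrolysine genes, TGA->U for selenoproteins; both
codons stay stops otherwise, so spurious opal readthrough cannot inflate
identity) — and the best local alignment per (transcript, gene) is kept.
A transcript counts as evidence of expression when its amino-acid identity
meets the screen threshold, 98% by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .align import align_proteins
from .codes import GeneticCodeTable, load_table, six_frame_translate
from .pathway import PathwayGeneSpec
from .sequences import NucleotideSequence

logger = logging.getLogger("gcescan.screen")

DEFAULT_THRESHOLD_PCT = 98.0
MIN_REPORT_LEN = 30
MIN_TRANSCRIPT_NT = 30


@dataclass(frozen=True)
class ExpressionEvidence:
    transcript_id: str
    spec_key: str
    frame: str               # +1..+3 / -1..-3
    aligned_len_aa: int
    identity_pct: float
    passes: bool
    covers_recoded_site: bool
    threshold_pct: float
    ref_span: tuple[int, int]


def _table_for(spec: PathwayGeneSpec, tables: dict) -> GeneticCodeTable:
    if spec.expects_recoding == "TAG>O":
        return tables["pyl_readthrough"]
    if spec.expects_recoding == "TGA>U":
        return tables["sec_readthrough"]
    return tables["bact11"]


def screen_transcripts(
    transcripts: list[NucleotideSequence],
    specs: list[PathwayGeneSpec],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_report_len: int = MIN_REPORT_LEN,
) -> list[ExpressionEvidence]:
    """Best-frame local-alignment evidence for every (transcript, gene) pair
    with at least ``min_report_len`` aligned residues."""
    tables = {name: load_table(name)
              for name in ("bact11", "pyl_readthrough", "sec_readthrough")}
    evidence: list[ExpressionEvidence] = []
    for t in transcripts:
        if len(t.seq) < MIN_TRANSCRIPT_NT:
            logger.warning("SKIP_SHORT_TRANSCRIPT id=%s len=%d", t.id, len(t.seq))
            continue
        for spec in specs:
            table = _table_for(spec, tables)
            best = None
            for frame_id, fragments in six_frame_translate(t, table):
                for frag in fragments:
                    if len(frag) < min_report_len:
                        continue
                    for ref in spec.references:
                        aln = align_proteins(frag, ref, mode="local")
                        if best is None or aln.score > best[0].score:
                            best = (aln, frame_id)
            if best is None:
                continue
            aln, frame_id = best
            if aln.aligned_columns < min_report_len:
                continue
            covers = (spec.expects_recoding is not None
                      and aln.ref_span[0] <= spec.recoded_index < aln.ref_span[1])
            evidence.append(ExpressionEvidence(
                transcript_id=t.id, spec_key=spec.key, frame=frame_id,
                aligned_len_aa=aln.aligned_columns,
                identity_pct=aln.identity_pct,
                passes=aln.identity_pct >= threshold_pct,
                covers_recoded_site=covers,
                threshold_pct=threshold_pct,
                ref_span=aln.ref_span))
    return evidence


def summarize_evidence(evidence: list[ExpressionEvidence]) -> dict:
    """Per-gene expression summary: a gene is expressed when any evidence
    row passes the threshold."""
    summary: dict = {}
    for ev in evidence:
        entry = summary.setdefault(ev.spec_key, {
            "n_transcripts": 0, "n_passing": 0, "best_identity_pct": 0.0,
            "expressed": False,
        })
        entry["n_transcripts"] += 1
        entry["n_passing"] += int(ev.passes)
        entry["best_identity_pct"] = max(entry["best_identity_pct"],
                                         round(ev.identity_pct, 2))
        entry["expressed"] = entry["expressed"] or ev.passes
    return summary
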
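"""Minimal GFF3 emission for gene calls, recoding events and RNA elements.

Internal coordinates are 0-based half-open on the forward strand; GFF3
output converts to 1-based closed.
"""

from __future__ import annotations

from pathlib import Path

from .orfs import GeneCall
from .recoding import RecodingEvent
from .secis import SecisHit
from .trna import TrnaHit

SOURCE = "gcescan"


def _attrs(pairs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items() if v != "")


def gene_line(g: GeneCall, feature_id: str, extra: dict | None = None) -> str:
    attrs = {"ID": feature_id, "table": g.table_name,
             "partial": "3prime" if g.partial_3prime else ""}
    attrs.update(extra or {})
    return "\t".join([g.contig_id, SOURCE, "CDS", str(g.start + 1), str(g.end),
                      ".", g.strand, "0", _attrs(attrs)])


def recoding_attrs(ev: RecodingEvent) -> dict:
    attrs = {"recoded_codon": ev.codon,
             "recoded_codon_index": str(ev.codon_index),
             "inserted_residue": ev.inserted_residue}
    if ev.conservation is not None:
        attrs["post_stop_identity_pct"] = f"{ev.conservation.aligned_identity_pct:.1f}"
        attrs["conserved"] = str(ev.conservation.conserved).lower()
    return attrs


def trna_line(h: TrnaHit, feature_id: str) -> str:
    attrs = {"ID": feature_id, "kind": h.kind, "anticodon": h.anticodon,
             "anticodon_rna": h.anticodon_rna,
             "variable_arm_len": str(h.variable_arm_len),
             "paired_bases": str(h.score)}
    return "\t".join([h.contig_id, SOURCE, "tRNA", str(h.start + 1), str(h.end),
                      str(h.score), h.strand, ".", _attrs(attrs)])


def secis_line(h: SecisHit, feature_id: str, strand: str) -> str:
    attrs = {"ID": feature_id, "tga_pos": str(h.tga_pos + 1),
             "offset_nt": str(h.offset_nt), "stem_len": str(h.stem_len),
             "loop_len": str(h.loop_len)}
    start = h.tga_pos + 1
    return "\t".join([h.contig_id, SOURCE, "stem_loop", str(start),
                      str(start + 2), str(h.score), strand, ".", _attrs(attrs)])


def write_gff3(lines: list[str], path: str | Path) -> None:
    Path(path).write_text("##gff-version 3\n" + "".join(l + "\n" for l in lines))
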
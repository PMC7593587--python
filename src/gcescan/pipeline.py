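"""End-to-end orchestration.

Genome analysis runs: first-pass ORF calling under the standard bacterial
code -> pathway classification -> *conditional* amber (TAG) readthrough
pass, gated on the pyrrolysine biosynthesis enzymes being present ->
post-stop conservation scoring -> conditional opal (TGA) pass gated on the
Sec machinery, with SECIS confirmation -> tRNA scan -> completeness verdict.
The expression screen runs independently on transcript input.

Pass gating is logged with stable prefixes (``READTHROUGH_PASS``,
``SEC_PASS``) so behavior is machine-checkable.  All outputs are
deterministic given input and configuration; every run directory receives
the serialized configuration and package version for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io_gff
from .codes import load_table
from .orfs import DEFAULT_MIN_AA, GeneCall, find_orfs
from .pathway import (CONSERVATION_THRESHOLD_PCT, CONSERVATION_WINDOW_AA,
                      InventoryRow, PathwayGeneSpec, PathwayInventory,
                      assess_post_stop_conservation, best_alignment_to_spec,
                      classify_pathway_genes, load_reference_set)
from .recoding import (RecodingEvent, find_readthrough_candidates,
                       requires_readthrough_pass)
from .screen import (DEFAULT_THRESHOLD_PCT, MIN_REPORT_LEN, screen_transcripts,
                     summarize_evidence)
from .secis import MAX_OFFSET, MIN_STEM, scan_secis
from .sequences import NucleotideSequence, read_fasta, read_transcripts, write_fasta
from .trna import scan_trna

logger = logging.getLogger("gcescan.pipeline")

_PCT_FIELDS = ("conservation_threshold_pct", "expression_threshold_pct")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a run; serialized into every report."""

    min_orf_aa: int = DEFAULT_MIN_AA
    max_events: int = 1
    conservation_window_aa: int = CONSERVATION_WINDOW_AA
    conservation_threshold_pct: float = CONSERVATION_THRESHOLD_PCT
    expression_threshold_pct: float = DEFAULT_THRESHOLD_PCT
    min_report_len: int = MIN_REPORT_LEN
    trna_anticodons: tuple = ("CTA", "TCA")
    secis_min_stem: int = MIN_STEM
    secis_max_offset: int = MAX_OFFSET
    first_pass_table: str = "bact11"
    amber_table: str = "pyl_readthrough"
    opal_table: str = "sec_readthrough"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be within [0, 100], got {v}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trna_anticodons"] = list(d["trna_anticodons"])
        return d


def _genes_by_contig(genes: list[GeneCall]) -> dict:
    out: dict = {}
    for g in genes:
        out.setdefault(g.contig_id, []).append(g)
    return out


def _update_row_with_event(row: InventoryRow, spec: PathwayGeneSpec,
                           ev: RecodingEvent, aln) -> None:
    row.status = "present"
    row.best_identity_pct = aln.identity_pct
    row.best_coverage_pct = aln.coverage_pct
    row.gene = ev.gene
    row.recoding = ev


def _run_amber_pass(contigs, genes_by_contig, rows, specs, cfg) -> list[RecodingEvent]:
    amber_specs = [s for s in specs if s.expects_recoding == "TAG>O"]
    table = load_table(cfg.amber_table)
    kept = []
    for contig in contigs:
        cands = find_readthrough_candidates(
            contig, genes_by_contig.get(contig.id, []), table,
            max_events=cfg.max_events)
        for ev in cands:
            best_spec, best_aln = None, None
            for s in amber_specs:
                aln, _ = best_alignment_to_spec(ev.gene.protein, s)
                if best_aln is None or aln.score > best_aln.score:
                    best_spec, best_aln = s, aln
            if best_spec is None:
                continue
            if (best_aln.identity_pct < best_spec.min_identity
                    or best_aln.coverage_pct < best_spec.min_coverage):
                continue
            report = assess_post_stop_conservation(
                ev, best_spec, window_aa=cfg.conservation_window_aa,
                threshold_pct=cfg.conservation_threshold_pct)
            ev.conservation = report
            if report.conserved:
                _update_row_with_event(rows[best_spec.key], best_spec, ev, best_aln)
                kept.append(ev)
                logger.info("AMBER_EVENT gene=%s codon_index=%d identity=%.1f",
                            best_spec.key, ev.codon_index,
                            report.aligned_identity_pct)
    return kept


def _run_opal_pass(contigs, genes_by_contig, rows, specs, cfg):
    opal_specs = [s for s in specs if s.expects_recoding == "TGA>U"]
    table = load_table(cfg.opal_table)
    kept_events, secis_hits = [], []
    for contig in contigs:
        cands = find_readthrough_candidates(
            contig, genes_by_contig.get(contig.id, []), table,
            max_events=cfg.max_events)
        for ev in cands:
            best_spec, best_aln = None, None
            for s in opal_specs:
                aln, _ = best_alignment_to_spec(ev.gene.protein, s)
                if best_aln is None or aln.score > best_aln.score:
                    best_spec, best_aln = s, aln
            if best_spec is None:
                continue
            if (best_aln.identity_pct < best_spec.min_identity
                    or best_aln.coverage_pct < best_spec.min_coverage):
                continue
            hits = scan_secis(ev.gene, contig, min_stem=cfg.secis_min_stem,
                              max_offset=cfg.secis_max_offset)
            if not hits:
                continue
            ev.conservation = assess_post_stop_conservation(
                ev, best_spec, window_aa=cfg.conservation_window_aa,
                threshold_pct=cfg.conservation_threshold_pct)
            _update_row_with_event(rows[best_spec.key], best_spec, ev, best_aln)
            kept_events.append(ev)
            secis_hits.extend(hits)
            logger.info("OPAL_EVENT gene=%s codon_index=%d secis_stem=%d",
                        best_spec.key, ev.codon_index, hits[0].stem_len)
    return kept_events, secis_hits


def analyze_genome(contigs: list[NucleotideSequence],
                   config: Optional[PipelineConfig] = None,
                   genome_id: Optional[str] = None) -> PathwayInventory:
    """Run the full genome analysis in memory; returns the inventory with
    verdict and missing components filled in."""
    cfg = config or PipelineConfig()
    if not contigs:
        raise ValueError("no contigs to analyze")
    specs = load_reference_set()
    first_table = load_table(cfg.first_pass_table)
    genes: list[GeneCall] = []
    for contig in contigs:
        genes.extend(find_orfs(contig, first_table, min_aa=cfg.min_orf_aa))
    logger.info("FIRST_PASS n_genes=%d", len(genes))
    rows = classify_pathway_genes([g.protein for g in genes], specs, genes=genes)
    by_contig = _genes_by_contig(genes)

    inv = PathwayInventory(
        genome_id=genome_id or contigs[0].id, rows=rows)
    if requires_readthrough_pass(rows):
        logger.info("READTHROUGH_PASS status=triggered reason=pyl-cassette-present")
        _run_amber_pass(contigs, by_contig, rows, specs, cfg)
    else:
        logger.info("READTHROUGH_PASS status=skipped reason=pyl-cassette-absent")

    sec_gate = all(rows[k].status == "present" for k in ("selA", "selB", "selD"))
    if sec_gate:
        logger.info("SEC_PASS status=triggered reason=sec-machinery-present")
        _, secis_hits = _run_opal_pass(contigs, by_contig, rows, specs, cfg)
        inv.secis_hits = secis_hits
    else:
        logger.info("SEC_PASS status=skipped reason=sec-machinery-absent")

    for contig in contigs:
        inv.trna_hits.extend(scan_trna(contig, cfg.trna_anticodons))
    for s in specs:
        row = rows[s.key]
        if (s.expects_recoding and row.status == "present"
                and row.recoding is None):
            row.note = f"no conserved in-frame {s.readthrough_codon}"
    return inv.finalize()


# ---------------------------------------------------------------------------
# file-level entry points

def _write_provenance(outdir: Path, cfg: PipelineConfig) -> None:
    from . import __version__
    payload = {"tool": "gcescan", "version": __version__,
               "config": cfg.to_dict()}
    (outdir / "config.json").write_text(json.dumps(payload, indent=2))


def run_genome_analysis(genome_fasta: str | Path, config: PipelineConfig,
                        outdir: str | Path) -> PathwayInventory:
    """Analyze a genome FASTA and write the inventory (TSV + JSON), gene
    calls and RNA elements (GFF3) and predicted proteins (FASTA)."""
    contigs = read_fasta(genome_fasta)
    if not contigs:
        raise ValueError(f"no FASTA records in {genome_fasta}")
    for c in contigs:
        if not c.seq:
            raise ValueError(f"empty sequence for record {c.id!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inv = analyze_genome(contigs, config)

    pd.DataFrame(inv.to_table()).to_csv(outdir / "inventory.tsv", sep="\t",
                                        index=False)
    (outdir / "inventory.json").write_text(inv.to_json())
    lines = []
    proteins = []
    k = 0
    for key, row in inv.rows.items():
        if row.gene is None:
            continue
        extra = io_gff.recoding_attrs(row.recoding) if row.recoding else {}
        extra["pathway_gene"] = key
        lines.append(io_gff.gene_line(row.gene, f"gene{k}", extra))
        proteins.append(dataclasses.replace(
            row.gene.protein, id=f"{inv.genome_id}|{key}",
            description=row.display_name))
        k += 1
    for i, h in enumerate(inv.trna_hits):
        lines.append(io_gff.trna_line(h, f"trna{i}"))
    for i, h in enumerate(inv.secis_hits):
        strand = next((row.gene.strand for row in inv.rows.values()
                       if row.gene and row.recoding
                       and row.recoding.codon == "TGA"), "+")
        lines.append(io_gff.secis_line(h, f"secis{i}", strand))
    io_gff.write_gff3(lines, outdir / "annotations.gff3")
    if proteins:
        write_fasta(proteins, outdir / "pathway_proteins.faa")
    _write_provenance(outdir, config)
    return inv


def run_expression_analysis(transcripts_path: str | Path,
                            config: PipelineConfig,
                            outdir: str | Path) -> dict:
    """Screen transcripts (FASTA/FASTQ) and write the evidence table and
    per-gene expression summary."""
    transcripts = read_transcripts(transcripts_path)
    if not transcripts:
        raise ValueError(f"no parseable records in {transcripts_path}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = load_reference_set()
    evidence = screen_transcripts(
        transcripts, specs, threshold_pct=config.expression_threshold_pct,
        min_report_len=config.min_report_len)
    rows = [dataclasses.asdict(ev) for ev in evidence]
    for r in rows:
        r["identity_pct"] = round(r["identity_pct"], 2)
        r["ref_span"] = f"{r['ref_span'][0]}-{r['ref_span'][1]}"
    pd.DataFrame(rows).to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    summary = summarize_evidence(evidence)
    (outdir / "expression_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    _write_provenance(outdir, config)
    return summary
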
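"""Pathway gene classification, conservation scoring and the per-genome
inventory.

The packaged reference set contains synthetic stand-in proteins for the
pyrrolysine cassette (pylB/C/D, the split pyrrolysyl-tRNA synthetase), the
Pyl-containing trimethylamine methyltransferase (mttB, O at a recorded
position), accessory genes (ramA, mttC), choline lyase (cutC/D), the Sec
machinery (selA/B/D), a Sec-containing grdA-like selenoprotein, a BCCT
transporter, and two query-only entries (mtbB, mtmB-like) used for
absence/negative reporting.

Classification replaces a profile-HMM search with pairwise local alignment
against the reference set under per-gene identity/coverage thresholds; the
profile search's E-value cutoff has no direct analogue here and thresholds
are configurable instead.  Each predicted protein is assigned to at most one
gene (its top-scoring one), and one top hit is retained per gene.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .align import AlignmentResult, align_proteins
from .orfs import GeneCall
from .recoding import RecodingEvent
from .sequences import ProteinSequence

logger = logging.getLogger("gcescan.pathway")

CONSERVATION_WINDOW_AA = 50
CONSERVATION_THRESHOLD_PCT = 40.0

#: components required for a "complete" pyrrolysine-pathway verdict
COMPLETENESS_COMPONENTS = (
    "pylB", "pylC", "pylD", "pylS_N", "pylS_C", "pyl_tRNA", "mttB_recoding",
)


@dataclass(frozen=True)
class PathwayGeneSpec:
    key: str
    display_name: str
    references: tuple[ProteinSequence, ...]
    min_identity: float
    min_coverage: float
    expects_recoding: Optional[str] = None   # "TAG>O" or "TGA>U"
    recoded_index: int = -1                  # residue index in the reference
    query_only: bool = False

    @property
    def inserted_residue(self) -> Optional[str]:
        return self.expects_recoding.split(">")[1] if self.expects_recoding else None

    @property
    def readthrough_codon(self) -> Optional[str]:
        return self.expects_recoding.split(">")[0] if self.expects_recoding else None


@dataclass
class ConservationReport:
    """Identity of the region following a repurposed codon vs the reference."""

    window_aa: int
    aligned_identity_pct: float
    reference_id: str
    conserved: bool
    threshold_pct: float
    degenerate: bool = False


@dataclass
class InventoryRow:
    spec_key: str
    display_name: str
    status: str                      # "present" | "absent"
    best_identity_pct: float = 0.0
    best_coverage_pct: float = 0.0
    gene: Optional[GeneCall] = None
    recoding: Optional[RecodingEvent] = None
    note: str = ""


@dataclass
class PathwayInventory:
    """Per-genome presence/absence table plus the completeness verdict."""

    genome_id: str
    rows: dict  # spec_key -> InventoryRow
    trna_hits: list = field(default_factory=list)
    secis_hits: list = field(default_factory=list)
    verdict: str = "negative"        # complete | partial | negative
    missing_components: list = field(default_factory=list)

    def finalize(self) -> "PathwayInventory":
        present = []
        missing = []
        for comp in COMPLETENESS_COMPONENTS:
            if comp == "pyl_tRNA":
                ok = any(h.kind == "pyl" for h in self.trna_hits)
            elif comp == "mttB_recoding":
                row = self.rows.get("mttB")
                ok = bool(row and row.recoding is not None
                          and row.recoding.conservation is not None
                          and row.recoding.conservation.conserved)
            else:
                row = self.rows.get(comp)
                ok = bool(row and row.status == "present")
            (present if ok else missing).append(comp)
        if not missing:
            self.verdict = "complete"
        elif present:
            self.verdict = "partial"
        else:
            self.verdict = "negative"
        self.missing_components = missing
        return self

    # -- reporting ----------------------------------------------------------

    def to_table(self) -> list[dict]:
        out = []
        for key, row in self.rows.items():
            out.append({
                "spec_key": key,
                "display_name": row.display_name,
                "status": row.status,
                "best_identity_pct": round(row.best_identity_pct, 2),
                "best_coverage_pct": round(row.best_coverage_pct, 2),
                "recoded": row.recoding is not None,
                "recoded_codon": row.recoding.codon if row.recoding else "",
                "recoded_codon_index": (row.recoding.codon_index
                                        if row.recoding else ""),
                "note": row.note,
            })
        return out

    def to_json(self) -> str:
        payload = {
            "genome_id": self.genome_id,
            "verdict": self.verdict,
            "missing_components": self.missing_components,
            "rows": self.to_table(),
            "n_trna_hits": len(self.trna_hits),
            "trna_kinds": sorted({h.kind for h in self.trna_hits}),
            "n_secis_hits": len(self.secis_hits),
        }
        return json.dumps(payload, indent=2)


def load_reference_set() -> list[PathwayGeneSpec]:
    """Load the packaged synthetic reference set (FASTA + sidecar TSV)."""
    data = resources.files("gcescan.data")
    proteins = {}
    for block in data.joinpath("pathway_refs.faa").read_text().split(">"):
        if not block.strip():
            continue
        header, *lines = block.splitlines()
        name = header.split()[0]
        proteins[name] = ProteinSequence(id=name, seq="".join(lines),
                                         description=header)
    specs = []
    reader = csv.DictReader(
        data.joinpath("pathway_refs.tsv").read_text().splitlines(), delimiter="\t")
    for rec in reader:
        expects = rec["expects_recoding"]
        specs.append(PathwayGeneSpec(
            key=rec["key"],
            display_name=rec["display_name"],
            references=(proteins[rec["key"]],),
            min_identity=float(rec["min_identity"]),
            min_coverage=float(rec["min_coverage"]),
            expects_recoding=None if expects == "-" else expects,
            recoded_index=int(rec["recoded_index"]),
            query_only=rec["query_only"] == "1",
        ))
    return specs


def best_alignment_to_spec(protein: ProteinSequence,
                           spec: PathwayGeneSpec) -> tuple[AlignmentResult, str]:
    """Best local alignment of a protein against a gene's references."""
    best = None
    best_ref = ""
    for ref in spec.references:
        aln = align_proteins(protein, ref, mode="local")
        if best is None or aln.score > best.score:
            best, best_ref = aln, ref.id
    return best, best_ref


def classify_pathway_genes(
    proteins: list[ProteinSequence],
    specs: list[PathwayGeneSpec],
    genes: Optional[list[GeneCall]] = None,
) -> dict:
    """Assign each protein to its top-scoring pathway gene and build rows.

    Ties between genes are broken by identity, then by gene order in
    ``specs``.  A gene is "present" when its best assigned protein clears the
    gene's identity and coverage thresholds; only the top hit per gene is
    retained.
    """
    rows = {
        s.key: InventoryRow(spec_key=s.key, display_name=s.display_name,
                            status="absent")
        for s in specs
    }
    spec_order = {s.key: i for i, s in enumerate(specs)}
    # best hit per spec: (score, identity, alignment, protein index)
    best_per_spec: dict = {}
    for pi, protein in enumerate(proteins):
        best_key = None
        best_tuple = None
        for s in specs:
            aln, _ = best_alignment_to_spec(protein, s)
            cand = (aln.score, aln.identity_pct, -spec_order[s.key])
            if best_tuple is None or cand > best_tuple:
                best_tuple, best_key, best_aln = cand, s.key, aln
        if best_key is None:
            continue
        prev = best_per_spec.get(best_key)
        cand = (best_aln.score, best_aln.identity_pct)
        if prev is None or cand > (prev[0].score, prev[0].identity_pct):
            best_per_spec[best_key] = (best_aln, pi)
    for s in specs:
        hit = best_per_spec.get(s.key)
        if hit is None:
            continue
        aln, pi = hit
        row = rows[s.key]
        row.best_identity_pct = aln.identity_pct
        row.best_coverage_pct = aln.coverage_pct
        if aln.identity_pct >= s.min_identity and aln.coverage_pct >= s.min_coverage:
            row.status = "present"
            row.gene = (genes[pi] if genes is not None
                        else proteins[pi].source_gene)
    return rows


def assess_post_stop_conservation(
    event: RecodingEvent,
    spec: PathwayGeneSpec,
    window_aa: int = CONSERVATION_WINDOW_AA,
    threshold_pct: float = CONSERVATION_THRESHOLD_PCT,
) -> ConservationReport:
    """Identity of the query segment following the repurposed codon against
    the reference segment following the reference's recoded residue.

    A quantitative stand-in for by-eye inspection of post-stop conservation:
    the two downstream windows (up to ``window_aa`` residues; shorter if the
    gene ends first) are globally aligned and the event is conserved when
    identity meets ``threshold_pct``.  A gene ending exactly at the recoded
    codon yields a degenerate, non-conserved report.
    """
    if spec.expects_recoding is None:
        raise ValueError(f"gene {spec.key!r} does not expect recoding")
    if event.inserted_residue != spec.inserted_residue:
        raise ValueError(
            f"event inserts {event.inserted_residue!r} but gene {spec.key!r} "
            f"expects {spec.inserted_residue!r}")
    q_seg = event.gene.protein.seq[event.codon_index + 1:
                                   event.codon_index + 1 + window_aa]
    if not q_seg:
        return ConservationReport(window_aa=0, aligned_identity_pct=0.0,
                                  reference_id="", conserved=False,
                                  threshold_pct=threshold_pct, degenerate=True)
    best: Optional[ConservationReport] = None
    for ref in spec.references:
        r_seg = ref.seq[spec.recoded_index + 1: spec.recoded_index + 1 + window_aa]
        if not r_seg:
            continue
        aln = align_proteins(q_seg, r_seg, mode="global")
        report = ConservationReport(
            window_aa=min(len(q_seg), len(r_seg)),
            aligned_identity_pct=aln.identity_pct,
            reference_id=ref.id,
            conserved=aln.identity_pct >= threshold_pct,
            threshold_pct=threshold_pct,
        )
        if best is None or report.aligned_identity_pct > best.aligned_identity_pct:
            best = report
    return best
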
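"""Synthetic genomes, implants and transcripts with known ground truth.

The generator emulates the shape of the real study inputs — bacterial
genome assemblies carrying a pyrrolysine biosynthesis cassette, a TMA
methyltransferase with a single in-frame TAG at a recorded position, a
Pyl-tRNA (CUA anticodon), Sec machinery with a TGA+SECIS selenoprotein,
decoys without recoding, and transcripts from these genes at controlled
amino-acid divergence — so every pipeline stage can be tested against a
manifest of implanted truth, without any downloads.

Three presets are provided:

``pyl_complete``
    full Pyl cassette + tRNA + recoded mttB + accessories + Sec machinery
    + grdA-like selenoprotein + BCCT + an mtmB-like decoy without TAG;
``pyl_no_trna``
    the same minus the Pyl-tRNA (the paper's ATCC 49260-like exception
    pattern, structurally);
``negative``
    decoys only.

All generators draw from a single explicitly seeded stream and are
byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .codes import load_table
from .pathway import PathwayGeneSpec, load_reference_set
from .sequences import NucleotideSequence, ProteinSequence, revcomp_str

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_GENOME_LENGTH = 42_000
DEFAULT_GC = 0.45
IMPLANT_MIN_SPACING = 100

#: six-frame stop cassette (its reverse complement is itself): placed around
#: every implant so open reading frames cannot run into the random background
STOP_GUARD = "TTAATTAATTAA"

_GENE_PLAN = ["pylB", "pylC", "pylD", "pylS_N", "pylS_C", "mttB", "ramA",
              "mttC", "cutC", "cutD", "grdA_like", "selA", "selB", "selD",
              "bcct"]

PRESETS = {
    "pyl_complete": _GENE_PLAN + ["pyl_tRNA", "mtmB_like_decoy"],
    "pyl_no_trna": _GENE_PLAN + ["mtmB_like_decoy"],
    "negative": ["mtmB_like_decoy", "bcct"],
}


@dataclass
class SyntheticManifest:
    """Ground truth for one synthetic genome and its simulated transcripts."""

    seed: int
    genome_id: str
    background: dict = field(default_factory=dict)
    implants: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticManifest":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticManifest":
        return cls.from_json(Path(path).read_text())

    def implant_for(self, spec_key: str) -> Optional[dict]:
        for imp in self.implants:
            if imp["spec_key"] == spec_key:
                return imp
        return None


# ---------------------------------------------------------------------------
# building blocks

def _synonymous_codons() -> dict:
    table = load_table("bact11")
    syn: dict = {}
    for codon, aa in table.codon_map.items():
        syn.setdefault(aa, []).append(codon)
    for aa in syn:
        syn[aa].sort()
    return syn


_SYN = _synonymous_codons()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous back-translation; O -> TAG, U -> TGA."""
    out = []
    for aa in protein:
        if aa == "O":
            out.append("TAG")
        elif aa == "U":
            out.append("TGA")
        else:
            codons = _SYN[aa]
            out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def mutate_protein(p: ProteinSequence | str, aa_divergence_pct: float,
                   seed: int) -> ProteinSequence:
    """Substitute each site independently with probability d/100 to a
    uniformly chosen *different* canonical residue; O and U are never
    mutated."""
    if not 0 <= aa_divergence_pct <= 100:
        raise ValueError("divergence must be in [0, 100]")
    seq = p.seq if isinstance(p, ProteinSequence) else p
    name = p.id if isinstance(p, ProteinSequence) else "protein"
    rng = np.random.default_rng(seed)
    out = []
    for aa in seq:
        if aa in "OU" or rng.random() >= aa_divergence_pct / 100.0:
            out.append(aa)
        else:
            choices = [c for c in CANONICAL_AA if c != aa]
            out.append(choices[rng.integers(len(choices))])
    return ProteinSequence(id=f"{name}|d{aa_divergence_pct:g}", seq="".join(out))


def _packaged_fasta(name: str) -> dict:
    text = resources.files("gcescan.data").joinpath(name).read_text()
    seqs = {}
    for block in text.split(">"):
        if block.strip():
            header, *lines = block.splitlines()
            seqs[header.split()[0]] = "".join(lines)
    return seqs


def implant_protein(spec_key: str,
                    specs: Optional[list[PathwayGeneSpec]] = None) -> ProteinSequence:
    """The protein a given implant encodes.  The mtmB-like decoy is the
    mtmB_like reference with its pyrrolysine replaced by lysine (no TAG)."""
    specs = specs if specs is not None else load_reference_set()
    by_key = {s.key: s for s in specs}
    if spec_key == "mtmB_like_decoy":
        ref = by_key["mtmB_like"].references[0]
        ridx = by_key["mtmB_like"].recoded_index
        return ProteinSequence(id="mtmB_like_decoy",
                               seq=ref.seq[:ridx] + "K" + ref.seq[ridx + 1:])
    return by_key[spec_key].references[0]


def _implant_sequence(spec_key: str, rng: np.random.Generator,
                      divergence_pct: float,
                      specs: list[PathwayGeneSpec]) -> tuple[str, Optional[int]]:
    """(implant nucleotide sequence in reading orientation, recoded codon
    index or None)."""
    if spec_key in ("pyl_tRNA", "sec_tRNA"):
        return _packaged_fasta("synthetic_trnas.fna")[spec_key], None
    if spec_key == "grdA_like" and divergence_pct == 0:
        # packaged CDS carries the engineered SECIS hairpin after its TGA
        by_key = {s.key: s for s in specs}
        return (_packaged_fasta("grdA_like_cds.fna")["grdA_like_cds"],
                by_key["grdA_like"].recoded_index)
    protein = implant_protein(spec_key, specs)
    if divergence_pct:
        protein = mutate_protein(protein, divergence_pct,
                                 int(rng.integers(2**31)))
    ridx = None
    for i, aa in enumerate(protein.seq):
        if aa in "OU":
            ridx = i
            break
    return back_translate(protein.seq, rng) + "TAA", ridx


def generate_genome(
    config: Optional[dict] = None,
    implant_plan: Optional[list] = None,
    preset: Optional[str] = None,
) -> tuple[NucleotideSequence, SyntheticManifest]:
    """Generate one synthetic contig with implants placed non-overlapping,
    >= 100 nt apart, on random strands, over an i.i.d. background with the
    configured GC fraction.

    ``config`` keys (all optional): ``length_nt``, ``gc_fraction``, ``seed``,
    ``divergence_pct`` (applied to gene implants).  ``implant_plan`` is a
    list of implant keys; ``preset`` picks a packaged plan instead.
    """
    cfg = {"length_nt": DEFAULT_GENOME_LENGTH, "gc_fraction": DEFAULT_GC,
           "seed": 0, "divergence_pct": 0.0}
    cfg.update(config or {})
    if not 0 < cfg["gc_fraction"] < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if preset is not None:
        implant_plan = PRESETS[preset]
    implant_plan = list(implant_plan or [])
    rng = np.random.default_rng(cfg["seed"])
    specs = load_reference_set()

    genome_id = f"synthetic_{preset or 'custom'}_seed{cfg['seed']}"
    implants = []
    pieces = []
    cursor = 0
    for key in implant_plan:
        seq, ridx = _implant_sequence(key, rng, cfg["divergence_pct"], specs)
        gap = IMPLANT_MIN_SPACING + int(rng.integers(0, 201))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + gap
        end = start + len(seq)
        oriented = seq if strand == "+" else revcomp_str(seq)
        # guards sit outside the recorded implant coordinates
        pieces.append((start - len(STOP_GUARD), STOP_GUARD + oriented + STOP_GUARD))
        implants.append({
            "spec_key": key, "contig_id": genome_id, "start": start,
            "end": end, "strand": strand,
            "recoded_codon_index": ridx,
            "divergence_pct_applied": cfg["divergence_pct"]
            if key not in ("pyl_tRNA", "sec_tRNA") else 0.0,
        })
        cursor = end
    required = cursor + IMPLANT_MIN_SPACING
    if cfg["length_nt"] < required:
        raise ValueError(
            f"length_nt={cfg['length_nt']} too short for the implant plan; "
            f"need at least {required} nt")
    background = random_background(rng, cfg["length_nt"], cfg["gc_fraction"])
    genome = list(background)
    for start, seq in pieces:
        genome[start:start + len(seq)] = seq
    contig = NucleotideSequence(id=genome_id, seq="".join(genome),
                                description=f"synthetic genome preset={preset}")
    manifest = SyntheticManifest(
        seed=int(cfg["seed"]), genome_id=genome_id,
        background={"length_nt": int(cfg["length_nt"]),
                    "gc_fraction": float(cfg["gc_fraction"])},
        implants=implants)
    return contig, manifest


# ---------------------------------------------------------------------------
# transcripts

TRANSCRIPT_WINDOW_AA = 150
MAX_PAD_NT = 5


def simulate_transcripts(
    manifest: SyntheticManifest,
    per_gene: int = 1,
    divergence_levels: list[float] = (0.0,),
    seed: int = 0,
    spec_keys: Optional[list[str]] = None,
) -> tuple[list[NucleotideSequence], SyntheticManifest]:
    """Back-translated transcript windows from the manifest's gene implants.

    For each selected gene implant, ``per_gene`` transcripts are emitted per
    divergence level: a window of the (optionally mutated) protein is
    back-translated with uniform synonymous codons (recoded sites to
    TAG/TGA), padded with a few random nucleotides, and emitted on a random
    strand; the reading frame is recorded in the manifest.  Windows of
    recoded proteins always span the recoded site.
    """
    if not manifest.implants:
        raise ValueError("manifest has no implants to transcribe")
    rng = np.random.default_rng(seed)
    specs = load_reference_set()
    transcripts: list[NucleotideSequence] = []
    records = []
    for imp in manifest.implants:
        key = imp["spec_key"]
        if key in ("pyl_tRNA", "sec_tRNA"):
            continue
        if spec_keys is not None and key not in spec_keys:
            continue
        protein = implant_protein(key, specs)
        for level in divergence_levels:
            for rep in range(per_gene):
                tid = f"tx_{key}_d{level:g}_{rep}"
                rec = _one_transcript(tid, key, protein, level, rng)
                transcripts.append(rec[0])
                records.append(rec[1])
    manifest.transcripts = manifest.transcripts + records
    return transcripts, manifest


def _one_transcript(tid: str, spec_key: str, protein: ProteinSequence,
                    level: float, rng: np.random.Generator):
    wlen = min(len(protein.seq), TRANSCRIPT_WINDOW_AA)
    ridx = next((i for i, aa in enumerate(protein.seq) if aa in "OU"), None)
    if ridx is not None:
        lo = max(0, ridx - wlen + 6)
        hi = min(len(protein.seq) - wlen, max(lo, ridx - 5))
    else:
        lo, hi = 0, len(protein.seq) - wlen
    start = int(rng.integers(lo, hi + 1))
    window = protein.seq[start:start + wlen]
    mutated = mutate_protein(window, level, int(rng.integers(2**31))).seq
    cds = back_translate(mutated, rng)
    pad5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, MAX_PAD_NT + 1))))
    pad3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, MAX_PAD_NT + 1))))
    forward = pad5 + cds + pad3
    if rng.random() < 0.5:
        seq, frame = forward, f"+{len(pad5) % 3 + 1}"
    else:
        seq, frame = revcomp_str(forward), f"-{len(pad5) % 3 + 1}"
    record = {
        "transcript_id": tid, "spec_key": spec_key, "frame": frame,
        "aa_divergence_pct": float(level),
        "window_start_aa": start, "window_len_aa": wlen,
        "covers_recoded_site": ridx is not None and start <= ridx < start + wlen,
    }
    return NucleotideSequence(id=tid, seq=seq), record
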
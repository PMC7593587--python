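"""One-off generator for the packaged synthetic data under src/gcescan/data/.

Everything this script writes is versioned in the repository; it is kept so
the provenance of the packaged files is reproducible:

* ``bact11.tab``, ``pyl_readthrough.tab``, ``sec_readthrough.tab`` —
  genetic-code tables (standard bacterial code 11 and its amber/opal
  readthrough variants).
* ``pathway_refs.faa`` + ``pathway_refs.tsv`` — synthetic stand-in reference
  proteins for the Pyl/Sec/TMA pathway gene set, with per-gene thresholds
  and recoded-residue positions in the sidecar table.
* ``grdA_like_cds.fna`` — the synthetic grdA-like coding sequence, designed
  nucleotide-first so that a SECIS-like hairpin sits 2 nt after its in-frame
  TGA; the packaged grdA-like reference protein is its readthrough
  translation.
* ``synthetic_trnas.fna`` — synthetic cloverleaf tRNA sequences with perfect
  arm pairing: a Pyl-tRNA (CTA anticodon) and a Sec-tRNA (TCA anticodon,
  16-nt variable arm).

Run from the repository root:  python scripts/build_packaged_data.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

DATA = Path(__file__).resolve().parent.parent / "src" / "gcescan" / "data"

AA20 = "ACDEFGHIKLMNPQRSTVWY"
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genetic-code tables

def build_tables() -> dict[str, str]:
    t11 = CodonTable.unambiguous_dna_by_id[11]
    sense = dict(t11.forward_table)  # codon -> residue, stops absent
    starts = ["ATG", "GTG", "TTG"]   # canonical bacterial starts only
    stops = sorted(t11.stop_codons)  # TAA, TAG, TGA

    def render(name, stop_set, readthrough):
        lines = [f"# synthetic genetic-code table: {name}", f"name {name}"]
        lines += [f"start {c}" for c in starts]
        lines += [f"stop {c}" for c in sorted(stop_set)]
        lines += [f"readthrough {c} {r}" for c, r in sorted(readthrough.items())]
        lines += [f"codon {c} {sense[c]}" for c in sorted(sense)]
        return "\n".join(lines) + "\n"

    return {
        "bact11": render("bact11", stops, {}),
        "pyl_readthrough": render(
            "pyl_readthrough", [c for c in stops if c != "TAG"], {"TAG": "O"}),
        "sec_readthrough": render(
            "sec_readthrough", [c for c in stops if c != "TGA"], {"TGA": "U"}),
    }


# ---------------------------------------------------------------------------
# reference proteins (synthetic stand-ins)

SPECS = [
    # key, display name, length, recoding ("TAG>O"/"TGA>U" or ""), recoded idx, query_only
    ("pylB", "3-methylornithine synthase", 350, "", -1, 0),
    ("pylC", "3-methylornithine--L-lysine ligase", 380, "", -1, 0),
    ("pylD", "3-methylornithyl-N6-L-lysine dehydrogenase", 320, "", -1, 0),
    ("pylS_N", "pyrrolysyl-tRNA synthetase N-terminal domain", 110, "", -1, 0),
    ("pylS_C", "pyrrolysyl-tRNA synthetase C-terminal domain", 270, "", -1, 0),
    ("mttB", "trimethylamine methyltransferase (Pyl-containing)", 460, "TAG>O", 230, 0),
    ("ramA", "methylamine methyltransferase corrinoid protein reductive activase", 500, "", -1, 0),
    ("mttC", "trimethylamine methyltransferase cognate corrinoid protein", 210, "", -1, 0),
    ("cutC", "choline trimethylamine-lyase", 420, "", -1, 0),
    ("cutD", "choline trimethylamine-lyase activating enzyme", 300, "", -1, 0),
    ("grdA_like", "glycine betaine reductase selenoprotein A homolog", 310, "TGA>U", 150, 0),
    ("selA", "L-seryl-tRNA(Sec) selenium transferase", 440, "", -1, 0),
    ("selB", "selenocysteine-specific translation elongation factor", 380, "", -1, 0),
    ("selD", "selenide, water dikinase", 340, "", -1, 0),
    ("bcct", "betaine/carnitine/choline transporter family protein", 500, "", -1, 0),
    ("mtbB", "dimethylamine methyltransferase", 450, "TAG>O", 220, 1),
    ("mtmB_like", "monomethylamine methyltransferase homolog", 440, "TAG>O", 215, 1),
]

MIN_IDENTITY = 35.0
MIN_COVERAGE = 70.0


def random_protein(rng: np.random.Generator, n: int) -> str:
    body = "".join(rng.choice(list(AA20), size=n - 1))
    return "M" + body


def make_grda_cds(rng: np.random.Generator, sense: dict[str, str]) -> tuple[str, str]:
    """Design the grdA-like CDS nucleotide-first: TGA at codon 150 followed
    2 nt later by a 9-bp perfect hairpin (loop 5 nt), all kept in frame and
    free of in-frame stops."""
    syn: dict[str, list[str]] = {}
    for codon, aa in sense.items():
        syn.setdefault(aa, []).append(codon)
    for aa in syn:
        syn[aa].sort()

    def bt(protein: str) -> str:
        return "".join(syn[aa][rng.integers(len(syn[aa]))] for aa in protein)

    part1 = random_protein(rng, 150)
    stem1 = "GGCAGGTCC"
    hairpin = "CA" + stem1 + "TTCGA" + revcomp(stem1) + "AG"  # 27 nt, 9 codons
    assert len(hairpin) % 3 == 0
    hp_res = "".join(sense[hairpin[i:i + 3]] for i in range(0, len(hairpin), 3))
    tail = "".join(rng.choice(list(AA20), size=310 - 151 - len(hp_res)))
    protein = part1 + "U" + hp_res + tail
    cds = bt(part1) + "TGA" + hairpin + bt(tail) + "TAA"
    return cds, protein


def build_reference_set() -> tuple[str, str, str]:
    rng = np.random.default_rng(7)
    t11 = CodonTable.unambiguous_dna_by_id[11]
    sense = dict(t11.forward_table)

    faa_lines: list[str] = []
    tsv_lines = ["key\tdisplay_name\tmin_identity\tmin_coverage\t"
                 "expects_recoding\trecoded_index\tquery_only"]
    grda_cds = ""
    for key, display, length, recoding, ridx, query_only in SPECS:
        if key == "grdA_like":
            grda_cds, protein = make_grda_cds(rng, sense)
            assert protein[ridx] == "U"
        else:
            protein = random_protein(rng, length)
            if recoding:
                residue = recoding.split(">")[1]
                protein = protein[:ridx] + residue + protein[ridx + 1:]
        faa_lines.append(f">{key} synthetic reference | {display}")
        faa_lines += [protein[i:i + 60] for i in range(0, len(protein), 60)]
        tsv_lines.append(
            f"{key}\t{display}\t{MIN_IDENTITY}\t{MIN_COVERAGE}\t"
            f"{recoding or '-'}\t{ridx}\t{query_only}")
    faa = "\n".join(faa_lines) + "\n"
    tsv = "\n".join(tsv_lines) + "\n"
    cds_fasta = ">grdA_like_cds synthetic CDS with in-frame TGA and SECIS-like hairpin\n"
    cds_fasta += "\n".join(grda_cds[i:i + 60] for i in range(0, len(grda_cds), 60)) + "\n"
    return faa, tsv, cds_fasta


# ---------------------------------------------------------------------------
# synthetic cloverleaf tRNAs

def make_trna(anticodon: str, variable_arm: str) -> str:
    acc5 = "GGCGGCA"
    d5 = "GCTC"
    ac5 = "CTGGA"
    t5 = "GGTCC"
    return (acc5 + "TA"
            + d5 + "AGATGGTA" + revcomp(d5)
            + "A"
            + ac5 + "TT" + anticodon + "AA" + revcomp(ac5)
            + variable_arm
            + t5 + "TTCGAAT" + revcomp(t5)
            + revcomp(acc5))


def build_trnas() -> str:
    pyl = make_trna("CTA", "TGTT")
    sec = make_trna("TCA", "ACGGTGGGACGTGGAC")
    assert len(pyl) == 71 and len(sec) == 83
    lines = [">pyl_tRNA synthetic pyrrolysine tRNA, CTA (CUA) anticodon", pyl,
             ">sec_tRNA synthetic selenocysteine tRNA, TCA (UCA) anticodon, long variable arm", sec]
    return "\n".join(lines) + "\n"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for name, text in build_tables().items():
        (DATA / f"{name}.tab").write_text(text)
    faa, tsv, cds = build_reference_set()
    (DATA / "pathway_refs.faa").write_text(faa)
    (DATA / "pathway_refs.tsv").write_text(tsv)
    (DATA / "grdA_like_cds.fna").write_text(cds)
    (DATA / "synthetic_trnas.fna").write_text(build_trnas())
    print(f"wrote packaged data under {DATA}")


if __name__ == "__main__":
    main()
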
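# Methods

## Problem and model

Pyrrolysine (Pyl, one-letter `O`) is inserted at in-frame TAG (amber)
codons by a dedicated tRNA with a CUA anticodon and a pyrrolysyl-tRNA
synthetase — split into N- and C-terminal genes in the organisms this
workflow targets. Selenocysteine (Sec, `U`) is inserted at in-frame TGA
(opal) codons when a SECIS stem-loop sits immediately downstream of the
recoded codon. A gene caller that treats every TAG/TGA as a terminator
splits such genes in two, so detection requires (i) re-prediction under a
modified genetic code and (ii) independent evidence that the readthrough
interpretation is real: conservation of the downstream region, presence of
the decoding machinery, and the cognate RNA elements.

`gcescan` implements this as a deterministic pipeline over explicit,
testable rules. Every probabilistic external tool of the original workflow
(GHMM gene calling, profile-HMM annotation, covariance-model tRNA search,
free-energy SECIS folding) is replaced by a self-contained counterpart
whose behavior can be checked against an exhaustive oracle; the replacements
are documented below with their parameters.

## Genetic-code tables

Tables are plain-text key-value files packaged with the code. `bact11` is
the standard bacterial code (stops TAA/TAG/TGA; starts ATG/GTG/TTG).
`pyl_readthrough` removes TAG from the stop set and maps it to `O`;
`sec_readthrough` does the same for TGA → `U`. A table must partition the
64 codons into coding/stop/readthrough roles; this is asserted at load.
Translation decisions: the gene's initiator codon is always emitted as Met;
internal start codons emit their table residue; codons containing `N` emit
`X` (never silently skipped — the original workflow does not state how
ambiguous bases were handled, so this is an explicit package choice);
lowercase and RNA (`U`) input are normalized on ingest.

## ORF scanning (first pass)

A deterministic maximal-ORF scanner stands in for a trained gene caller
(re-implementing one is out of scope, and synthetic genomes have no codon
bias to exploit). A gene starts at a start codon, ends at the first
in-frame terminator, and within each (strand, frame, terminator) group only
the longest ORF is kept; default minimum length 50 aa. ORFs reaching the
contig edge are flagged 3'-partial; genes lacking a start codon at the 5'
contig edge are not called (the 5'-partial flag exists on the data type for
completeness). Coordinates are 0-based half-open on the forward strand
everywhere in memory; GFF3 output converts to 1-based closed. The scanner
is verified against an exhaustive every-position scan on random contigs.

## Readthrough pass

Run only when pylB, pylC and pylD are all classified present (mirroring the
conditional re-prediction of the original workflow); gating is logged with
a stable `READTHROUGH_PASS` prefix. Every first-pass gene terminated by the
readthrough codon is extended through it to the next hard stop (default at
most one readthrough event per gene — the targeted methyltransferases carry
a single conserved amber — configurable via `max_events`). The event
records the consumed codon's in-gene index and links the two first-pass
genes it fuses; extension off the contig keeps the candidate with a
3'-partial flag. Candidates are emitted for *all* amber-terminated genes;
what gets reported as recoded is decided by classification plus
conservation, replacing by-eye inspection with a quantitative rule.

The opal (Sec) pass works identically but is gated on selA+selB+selD
presence and additionally requires a SECIS-like hairpin downstream of the
consumed TGA. This gating is a package choice: it keeps genomes without any
Sec machinery free of readthrough extension.

## Homology and conservation

Pairwise alignment uses affine-gap dynamic programming (Biopython's
`PairwiseAligner`) with BLOSUM62 extended to `O` and `U`: +6 self-match,
−4 against everything else, so a recoded residue only rewards alignment to
a reference recoded at the same position. Gap scores −11/−1 with the
convention that the first gap position costs the open score. Identity is
matches over aligned columns excluding end gaps; coverage is the aligned
reference span over reference length. The DP optimum is verified against an
independent plain-recursion Gotoh oracle.

Classification assigns each predicted protein to its top-scoring pathway
gene (ties: identity, then gene order); a gene is present when its best hit
clears that gene's thresholds (defaults 35% identity, 70% coverage — the
profile-HMM E-value cutoff of the original workflow has no direct analogue
here and is documented as replaced). Lowering a threshold can only turn
genes present, never absent.

Post-stop conservation aligns the query segment after the repurposed codon
against the reference segment after its recoded residue: window 50 aa
(shorter at gene ends; a gene ending exactly at the recoded codon yields a
degenerate, non-conserved report), threshold 40% identity. Both values are
explicit stand-ins for a by-eye judgment and are configurable; 40% sits far
above the ~5–25% identity that random or frame-shifted downstream sequence
achieves under this aligner, and far below the near-100% of a true
continuation.

## RNA elements

The tRNA scanner enumerates cloverleaf geometries anchored at occurrences
of the target anticodon (acceptor stem 7 bp, D stem 4 bp with 7–11 nt loop,
anticodon stem 5 bp with the anticodon centered in a 7 nt loop, variable
arm 4–23 nt, T stem 5 bp with 7 nt loop; total length 70–93 nt). Pairing
counts allow G-U wobble. A hit requires per-arm minima (acceptor ≥6/7,
D ≥3/4, anticodon ≥4/5, T ≥4/5) and a minimum total of paired stem bases,
default 21/21. The total was calibrated on 6 Mb of random 50% GC sequence:
requiring 19 admits ~4 chance hits per Mb and 20 about 0.7, while fully
paired stems produced none; the packaged synthetic tRNAs have fully paired
stems, so detection of the benchmark is unaffected. Real tRNAs with
imperfect stems would need a lower `min_total_paired`; the scanner is a
benchmark-grade stand-in for covariance-model search, not a replacement for
it. Hits are classified pyl (CTA anticodon) or sec (TCA anticodon and
variable arm ≥10 nt); overlapping hits collapse to the best-scoring one,
and anticodons are reported in both DNA (CTA/TCA) and RNA (CUA/UCA) form.

The SECIS search replaces free-energy folding with paired-base
maximization: within 15 nt downstream of an in-frame TGA (coding strand)
it finds the longest fully paired stem (G-U allowed, loop 3–12 nt,
stem ≥7 bp by default) and reports the best hairpin per TGA, preferring
smaller offsets then smaller loops on ties. Both scanners are deterministic
and oracle-checked.

## Expression screen

Transcripts are six-frame translated with frame-dependent stop splitting;
the translation table is chosen per target gene (TAG→O for pyrrolysine
genes, TGA→U for selenoproteins, standard code otherwise), so opal
readthrough can never inflate identity against a non-selenoprotein. The
best local alignment per (transcript, gene) is kept; rows need ≥30 aligned
residues (the accompanying minimum alignment length is not specified by the
original workflow, so it is an explicit parameter), and a transcript passes
at ≥98% amino-acid identity — minimum-threshold semantics, so exactly 98.0
passes. Transcripts under 30 nt are skipped with a logged warning.

## Synthetic data

The generator emulates the *shape* of the real study inputs: one contig of
i.i.d. background at a configurable GC fraction (default 0.45, typical of
the targeted taxa) with non-overlapping implants ≥100 nt apart on random
strands. The packaged reference proteins double as implant sources, at 0%
divergence by default so detection tests are exact, with a divergence knob
for sensitivity studies. Each implant is wrapped in a 12 nt six-frame stop
cassette so background sequence can never extend an implanted ORF — without
it, a chance upstream in-frame ATG shifts the recoded codon index. Three
presets: `pyl_complete` (full cassette, tRNA, recoded mttB, accessories,
Sec machinery with SECIS'd selenoprotein, BCCT, and an mtmB-like decoy with
the recoded position substituted so it carries no TAG), `pyl_no_trna`
(minus the tRNA) and `negative` (decoys only). Default genome length
42 kb — comfortably above the ~20 kb of implants.

The grdA-like selenoprotein is designed CDS-first: its packaged coding
sequence carries an engineered 9 bp hairpin 2 nt after the in-frame TGA,
and the reference *protein* is that CDS's readthrough translation, so the
implanted genome is guaranteed to contain both the recoded codon and its
SECIS element. Transcript simulation back-translates windows of the
implant proteins with uniform synonymous codon choice (recoded sites to
TAG/TGA), applies site-independent substitution at the requested amino-acid
divergence (recoded residues never mutate), pads with ≤5 random nt, and
emits on a random strand with the true reading frame recorded in the
manifest. All generators draw from one explicitly seeded stream and are
byte-deterministic.

What the generator does **not** emulate: codon usage and GC skew of real
genomes, sequencing error and indels, partial/fragmented genes, assembly
artifacts, and homologs at intermediate divergence. Passing tests therefore
demonstrate correctness of the detection logic under known ground truth,
not sensitivity on real data.

## Verdict

`complete` requires pylB, pylC, pylD, both synthetase genes, a pyl-tRNA hit
and a conserved recoding event on mttB; `partial` means some but not all of
these; `negative` none. Accessory genes (ramA, mttC, cutC/D, bcct, Sec
machinery) are reported informationally and do not enter the verdict —
whether they should is genuinely open, and excluding them keeps the verdict
aligned with the pyrrolysine pathway itself. Query-only entries (mtbB,
mtmB-like) support absence/negative reporting: a present gene that expects
recoding but shows none carries an explicit "no conserved in-frame TAG"
note.

## Problem sizes

Defaults used by the test suite and the acceptance script: 42 kb genomes
(20 replicate seeds for ground-truth recovery), 2 kb contigs for ORF-oracle
equivalence, ≤60 aa pairs for alignment-oracle equivalence, 200 transcripts
per divergence level for the expression screen, and 1 Mb of random sequence
for tRNA-scanner specificity. These sizes exercise every code path while
keeping a full run to a few minutes on one CPU.
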
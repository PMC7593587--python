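"""Anticodon-constrained cloverleaf tRNA scanning.

A heuristic arm-pairing scanner stands in for covariance-model tRNA search.
The cloverleaf model is a fixed arm layout (5'->3'):

    acceptor 5' (7) | spacer (2) | D stem 5' (4) | D loop (7-11) |
    D stem 3' (4) | spacer (1) | anticodon stem 5' (5) |
    anticodon loop (7, anticodon centered) | anticodon stem 3' (5) |
    variable arm (4-23) | T stem 5' (5) | T loop (7) | T stem 3' (5) |
    acceptor 3' (7)

Candidate geometries are enumerated at every occurrence of a target
anticodon (every model hit must contain the target trimer at the loop
center, so anchoring on it is exhaustive).  Default stringency — per-arm
paired-base minima plus a minimum total paired-base count across the four
stems, G-T wobble allowed — is calibrated so that random sequence at
megabase scale yields no hits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import NucleotideSequence, revcomp_str

ACC_LEN, D_STEM, AC_STEM, T_STEM = 7, 4, 5, 5
SPACER1, SPACER2, T_LOOP = 2, 1, 7
D_LOOP_RANGE = range(7, 12)
VAR_RANGE = range(4, 24)

MIN_ACC_PAIRED = 6
MIN_D_PAIRED = 3
MIN_AC_PAIRED = 4
MIN_T_PAIRED = 4
# calibrated on multi-Mb random sequence: 19 admits ~4 chance hits per Mb,
# 20 ~0.7, 21 (fully paired stems) none observed in 6 Mb
MIN_TOTAL_PAIRED = 21

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def _paired(stem5: str, stem3: str) -> int:
    """Paired-base count between a stem's two strands (G-T wobble allowed)."""
    n = len(stem5)
    return sum((stem5[k], stem3[n - 1 - k]) in _PAIRS for k in range(n))


@dataclass(frozen=True)
class TrnaHit:
    contig_id: str
    start: int                  # forward strand, 0-based half-open
    end: int
    strand: str
    anticodon: str              # DNA alphabet, 5'->3' in the loop
    arm_scores: dict            # per-arm paired-base counts
    variable_arm_len: int
    score: int                  # total paired bases across the four stems

    @property
    def kind(self) -> str:
        if self.anticodon == "CTA":
            return "pyl"
        if self.anticodon == "TCA" and self.variable_arm_len >= 10:
            return "sec"
        return "other"

    @property
    def anticodon_rna(self) -> str:
        return self.anticodon.replace("T", "U")


def _evaluate_anchor(ss: str, loop_start: int, anticodon: str,
                     min_total: int = MIN_TOTAL_PAIRED):
    """Best cloverleaf geometry for an anticodon loop starting at loop_start."""
    ac5 = ss[loop_start - AC_STEM: loop_start]
    ac3 = ss[loop_start + 7: loop_start + 7 + AC_STEM]
    if len(ac5) < AC_STEM or len(ac3) < AC_STEM:
        return None
    ac_paired = _paired(ac5, ac3)
    if ac_paired < MIN_AC_PAIRED:
        return None
    best = None
    for d_loop in D_LOOP_RANGE:
        up_len = ACC_LEN + SPACER1 + D_STEM + d_loop + D_STEM + SPACER2 + AC_STEM
        start = loop_start - up_len
        if start < 0:
            continue
        acc5 = ss[start: start + ACC_LEN]
        d5_at = start + ACC_LEN + SPACER1
        d5 = ss[d5_at: d5_at + D_STEM]
        d3 = ss[d5_at + D_STEM + d_loop: d5_at + D_STEM + d_loop + D_STEM]
        d_paired = _paired(d5, d3)
        if d_paired < MIN_D_PAIRED:
            continue
        for var in VAR_RANGE:
            t5_at = loop_start + 7 + AC_STEM + var
            t5 = ss[t5_at: t5_at + T_STEM]
            t3 = ss[t5_at + T_STEM + T_LOOP: t5_at + T_STEM + T_LOOP + T_STEM]
            if len(t3) < T_STEM:
                break
            t_paired = _paired(t5, t3)
            if t_paired < MIN_T_PAIRED:
                continue
            acc3_at = t5_at + T_STEM + T_LOOP + T_STEM
            acc3 = ss[acc3_at: acc3_at + ACC_LEN]
            if len(acc3) < ACC_LEN:
                break
            acc_paired = _paired(acc5, acc3)
            if acc_paired < MIN_ACC_PAIRED:
                continue
            total = acc_paired + d_paired + ac_paired + t_paired
            if total < min_total:
                continue
            cand = (total, -d_loop, -var, start, acc3_at + ACC_LEN,
                    {"acceptor": acc_paired, "d_arm": d_paired,
                     "anticodon_arm": ac_paired, "t_arm": t_paired})
            if best is None or cand[:3] > best[:3]:
                best = cand
    return best


def _scan_one_strand(ss: str, contig_id: str, strand: str, total: int,
                     target_anticodons, min_total: int) -> list[TrnaHit]:
    hits = []
    for anticodon in sorted(target_anticodons):
        pos = ss.find(anticodon)
        while pos != -1:
            loop_start = pos - 2   # anticodon centered in a 7-nt loop
            if loop_start >= AC_STEM:
                found = _evaluate_anchor(ss, loop_start, anticodon, min_total)
                if found is not None:
                    total_paired, neg_dloop, neg_var, s, e, arms = found
                    if strand == "+":
                        start, end = s, e
                    else:
                        start, end = total - e, total - s
                    hits.append(TrnaHit(
                        contig_id=contig_id, start=start, end=end,
                        strand=strand, anticodon=anticodon, arm_scores=arms,
                        variable_arm_len=-neg_var, score=total_paired))
            pos = ss.find(anticodon, pos + 1)
    return hits


def _collapse(hits: list[TrnaHit]) -> list[TrnaHit]:
    """Keep best-scoring hits; discard any overlapping a kept hit by more
    than 50% of the shorter of the two."""
    kept: list[TrnaHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.start, x.end, x.strand)):
        clash = False
        for k in kept:
            if k.contig_id != h.contig_id:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            shorter = min(k.end - k.start, h.end - h.start)
            if ov > 0.5 * shorter:
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda x: (x.start, x.end, x.strand))
    return kept


def scan_trna(contig: NucleotideSequence,
              target_anticodons=("CTA", "TCA"),
              min_total_paired: int = MIN_TOTAL_PAIRED) -> list[TrnaHit]:
    """Scan both strands for cloverleaf structures carrying one of the
    target anticodons; overlapping hits are collapsed to the best one."""
    bad = [a for a in target_anticodons if len(a) != 3 or set(a) - set("ACGT")]
    if bad:
        raise ValueError(f"invalid anticodon(s): {bad}")
    hits = _scan_one_strand(contig.seq, contig.id, "+", len(contig.seq),
                            target_anticodons, min_total_paired)
    hits += _scan_one_strand(revcomp_str(contig.seq), contig.id, "-",
                             len(contig.seq), target_anticodons, min_total_paired)
    return _collapse(hits)
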
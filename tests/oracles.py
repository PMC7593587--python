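"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (plain loops
and recursions over every position/state) and shares no code paths with the
implementation; only raw data (codon maps, substitution scores) is reused.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# translation / six-frame

def _residue(codon: str, table) -> str:
    if "N" in codon:
        return "X"
    if codon in table.readthrough:
        return table.readthrough[codon]
    return table.codon_map[codon]


def six_frame_fragments(seq: str, table) -> list[tuple[str, list[str]]]:
    """Translate every strand/offset independently, splitting at stops."""
    out = []
    for strand, ss in (("+", seq), ("-", rc(seq))):
        for offset in range(3):
            frags, cur = [], []
            for i in range(offset, len(ss) - 2, 3):
                codon = ss[i:i + 3]
                if codon in table.stops:
                    if cur:
                        frags.append("".join(cur))
                    cur = []
                else:
                    cur.append(_residue(codon, table))
            if cur:
                frags.append("".join(cur))
            out.append((f"{strand}{offset + 1}", frags))
    return out


# ---------------------------------------------------------------------------
# exhaustive ORF scan

def brute_force_orfs(seq: str, table, min_aa: int):
    """Every start-codon position extended to its first in-frame stop; per
    (strand, frame, terminator) only the longest survivor.  Returns a set of
    (start, end, strand, protein, partial_3prime) in forward coordinates."""
    candidates = {}
    for strand, ss in (("+", seq), ("-", rc(seq))):
        n = len(ss)
        for pos in range(n - 2):
            if ss[pos:pos + 3] not in table.starts:
                continue
            i = pos
            stop_at = None
            while i + 3 <= n:
                if ss[i:i + 3] in table.stops and i > pos:
                    stop_at = i
                    break
                if ss[i:i + 3] in table.stops and i == pos:
                    break
                i += 3
            if ss[pos:pos + 3] in table.stops:
                continue
            if stop_at is not None:
                end_local = stop_at + 3
                n_res = (stop_at - pos) // 3
                partial = False
            else:
                end_local = pos + 3 * ((n - pos) // 3)
                n_res = (end_local - pos) // 3
                partial = True
            if n_res < min_aa:
                continue
            protein = "M" + "".join(
                _residue(ss[k:k + 3], table)
                for k in range(pos + 3, pos + 3 * n_res, 3))
            key = (strand, pos % 3, end_local, partial)
            prev = candidates.get(key)
            if prev is None or pos < prev[0]:
                candidates[key] = (pos, end_local, strand, protein, partial)
    out = set()
    for pos, end_local, strand, protein, partial in candidates.values():
        if strand == "+":
            start, end = pos, end_local
        else:
            start, end = len(seq) - end_local, len(seq) - pos
        out.add((start, end, strand, protein, partial))
    return out


# ---------------------------------------------------------------------------
# affine-gap alignment score (Gotoh, plain recursion with memoisation)

NEG = float("-inf")


def gotoh_score(a: str, b: str, matrix, mode: str = "global",
                open_gap: float = -11.0, extend_gap: float = -1.0) -> float:
    """Optimal affine-gap alignment score; first gap position costs
    ``open_gap``, each subsequent one ``extend_gap`` (matching the
    implementation's stated convention).  Global mode penalizes end gaps."""
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state 0: a_i aligned to b_j; 1: a_i against gap; 2: b_j against gap
        if state == 0:
            if i == 0 or j == 0:
                return NEG if (i, j) != (0, 0) else 0.0
            prev = max(best(i - 1, j - 1, s) for s in range(3))
            local_floor = 0.0 if mode == "local" else NEG
            return max(prev, local_floor) + matrix[a[i - 1], b[j - 1]]
        if state == 1:
            if i == 0:
                return NEG
            return max(best(i - 1, j, 0) + open_gap,
                       best(i - 1, j, 1) + extend_gap,
                       best(i - 1, j, 2) + open_gap)
        if j == 0:
            return NEG
        return max(best(i, j - 1, 0) + open_gap,
                   best(i, j - 1, 2) + extend_gap,
                   best(i, j - 1, 1) + open_gap)

    # allow alignments starting at (0,0) with leading gaps in global mode
    def m0(i, j):
        return max(best(i, j, s) for s in range(3))

    if mode == "global":
        return m0(n, m)
    top = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            top = max(top, best(i, j, 0))
    return top


# ---------------------------------------------------------------------------
# exhaustive cloverleaf window scan

ARM = dict(acc=7, sp1=2, d=4, sp2=1, ac=5, tloop=7, t=5)


def _pairs(x: str, y: str) -> bool:
    return _COMP.get(x) == y or {x, y} == {"G", "T"}


def _stem_paired(s5: str, s3: str) -> int:
    return sum(_pairs(s5[k], s3[len(s5) - 1 - k]) for k in range(len(s5)))


def cloverleaf_candidates(seq: str, targets, min_total: int = 21):
    """All (strand, start, end, anticodon, total_paired) where some geometry
    passes the default stringency; enumerated over every window position and
    geometry, both strands."""
    found = []
    for strand, ss in (("+", seq), ("-", rc(seq))):
        n = len(ss)
        for start in range(n):
            for d_loop in range(7, 12):
                ac5_at = start + 7 + 2 + 4 + d_loop + 4 + 1
                loop_at = ac5_at + 5
                if loop_at + 12 > n:
                    continue
                anticodon = ss[loop_at + 2: loop_at + 5]
                if anticodon not in targets:
                    continue
                if _stem_paired(ss[ac5_at:ac5_at + 5],
                                ss[loop_at + 7: loop_at + 12]) < 4:
                    continue
                if _stem_paired(ss[start + 9:start + 13],
                                ss[start + 13 + d_loop:start + 17 + d_loop]) < 3:
                    continue
                for var in range(4, 24):
                    t_at = loop_at + 12 + var
                    end = t_at + 5 + 7 + 5 + 7
                    if end > n:
                        break
                    acc_p = _stem_paired(ss[start:start + 7], ss[end - 7:end])
                    d_p = _stem_paired(ss[start + 9:start + 13],
                                       ss[start + 13 + d_loop:start + 17 + d_loop])
                    ac_p = _stem_paired(ss[ac5_at:ac5_at + 5],
                                        ss[loop_at + 7:loop_at + 12])
                    t_p = _stem_paired(ss[t_at:t_at + 5],
                                       ss[t_at + 12:t_at + 17])
                    if acc_p < 6 or d_p < 3 or ac_p < 4 or t_p < 4:
                        continue
                    total = acc_p + d_p + ac_p + t_p
                    if total < min_total:
                        continue
                    if strand == "+":
                        f_start, f_end = start, end
                    else:
                        f_start, f_end = len(seq) - end, len(seq) - start
                    found.append((strand, f_start, f_end, anticodon, total))
    return found


# ---------------------------------------------------------------------------
# exhaustive hairpin maximization

def best_hairpin(region: str, min_stem: int = 7, max_offset: int = 15,
                 max_stem: int = 20):
    """(stem, offset, loop) of the maximal fully paired hairpin; ties prefer
    smaller offset then smaller loop.  None if no stem >= min_stem exists."""
    best = None
    for stem in range(max_stem, min_stem - 1, -1):
        for offset in range(max_offset + 1):
            for loop in range(3, 13):
                end = offset + 2 * stem + loop
                if end > len(region):
                    continue
                s5 = region[offset:offset + stem]
                s3 = region[offset + stem + loop:end]
                if all(_pairs(s5[k], s3[stem - 1 - k]) for k in range(stem)):
                    if best is None or (stem, -offset, -loop) > (
                            best[0], -best[1], -best[2]):
                        best = (stem, offset, loop)
        if best is not None:
            return best
    return best
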
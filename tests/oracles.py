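"""Independent brute-force oracles used to validate the optimized engines.

Each oracle is deliberately naive (exhaustive scans, enumeration) and shares
no code with the implementation it checks.
"""

from __future__ import annotations

import re
from functools import lru_cache

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def diagonal_scan_best(
    query: str, subject: str, match: int = 1, mismatch: int = -2, both_strands: bool = True
) -> int:
    """Maximum ungapped window score over all diagonals and both strands."""
    best = 0
    strands = [subject, revcomp(subject)] if both_strands else [subject]
    for sseq in strands:
        m, n = len(query), len(sseq)
        for d in range(-(n - 1), m):
            lo, hi = max(0, d), min(m, n + d)
            cur = 0
            for i in range(lo, hi):
                hit = query[i] == sseq[i - d] and query[i] != "N"
                cur = max(0, cur + (match if hit else mismatch))
                best = max(best, cur)
    return best


def regex_ssr_scan(seq: str, min_repeats: dict[int, int]) -> set[tuple[str, int, int]]:
    """All maximal primitive perfect tandem runs as (motif, start, count)."""

    def primitive(motif: str) -> bool:
        k = len(motif)
        return not any(k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k))

    found: set[tuple[str, int, int]] = set()
    for k, minimum in min_repeats.items():
        for m in re.finditer(rf"([ACGT]{{{k}}})\1{{{minimum - 1},}}", seq):
            motif = m.group(1)
            if not primitive(motif):
                continue
            count = (m.end() - m.start()) // k
            found.add((motif, m.start(), count))
    return found


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested base pairing by exhaustive recursion (length <= ~14)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        result = best(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):  # j paired with k
            if (seq[k], seq[j]) in _PAIRS:
                outside = best(i, k - 1) if k > i else 0
                result = max(result, outside + 1 + best(k + 1, j - 1))
        return result

    return best(0, len(seq) - 1)


def hybridize_offset_scan(seq_a: str, seq_b: str, e_gc=-3.0, e_au=-2.0, e_gu=-1.0, mm=1.0):
    """Exhaustive-offset duplex scan; returns (best dG, overlap length)."""
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    r = long_[::-1]
    energy = {}
    for x, y in [("A", "T"), ("T", "A")]:
        energy[(x, y)] = e_au
    for x, y in [("G", "C"), ("C", "G")]:
        energy[(x, y)] = e_gc
    for x, y in [("G", "T"), ("T", "G")]:
        energy[(x, y)] = e_gu
    best = None
    for offset in range(-(len(short) - 1), len(r)):
        dg, overlap = 0.0, 0
        for i in range(len(short)):
            j = i + offset
            if 0 <= j < len(r):
                dg += energy.get((short[i], r[j]), mm)
                overlap += 1
        if overlap and (best is None or dg < best[0]):
            best = (dg, overlap)
    return best


def six_frame_orfs(seq: str) -> list[tuple[int, int]]:
    """All complete ATG..stop spans (aa length, frame sign) by regex scan."""
    out = []
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for offset in range(3):
            codons = [s[i : i + 3] for i in range(offset, len(s) - 2, 3)]
            starts = []
            for idx, codon in enumerate(codons):
                if codon == "ATG":
                    starts.append(idx)
                elif codon in ("TAA", "TAG", "TGA"):
                    for st in starts:
                        out.append((idx - st, strand * (offset + 1)))
                    starts = []
    return out
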
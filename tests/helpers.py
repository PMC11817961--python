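"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results by exhaustive enumeration rather
than reusing the library's scanning logic.
"""

from __future__ import annotations

import itertools

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _primitive(m: str) -> bool:
    return all(
        not (len(m) % d == 0 and m == m[:d] * (len(m) // d))
        for d in range(1, len(m))
    )


def brute_force_ssrs(seq: str, thresholds: dict[int, int]):
    """Exhaustively test every (position, unit length) pair for a
    qualifying maximal perfect repeat, then resolve overlaps by the
    documented rules: per unit length keep the leftmost of overlapping
    runs; across unit lengths drop intervals nested inside another
    locus (ties to the shorter unit).

    Returns a set of (start, end, motif) with 1-based inclusive coords.
    """
    seq = seq.upper()
    n = len(seq)
    per_k: dict[int, list[tuple[int, int, str]]] = {}
    for k in range(1, 7):
        cands = []
        for i in range(n - k * thresholds[k] + 1):
            motif = seq[i : i + k]
            if len(motif) < k or "N" in motif or not _primitive(motif):
                continue
            if i >= k and seq[i - k : i] == motif:
                continue  # not left-maximal by a full unit
            j = i + k
            while j + k <= n and seq[j : j + k] == motif:
                j += k
            r = (j - i) // k
            if r >= thresholds[k]:
                cands.append((i + 1, i + r * k, motif))
        kept, last_end = [], 0
        for c in sorted(cands):
            if c[0] > last_end:
                kept.append(c)
                last_end = c[1]
        per_k[k] = kept
    merged = sorted(
        (c for k in per_k for c in per_k[k]),
        key=lambda c: (c[0], -c[1], len(c[2])),
    )
    out, cover_end = set(), 0
    for c in merged:
        if c[1] <= cover_end:
            continue
        out.add(c)
        cover_end = max(cover_end, c[1])
    return out


def brute_force_epcr(genome: dict[str, str], fwd: str, rev: str,
                     max_product: int, max_mm: int = 0):
    """All-positions e-PCR scan.  Returns a set of
    (chrom, start, end, strand) with 1-based inclusive outer spans."""

    def sites(seq, primer, tail):
        m = len(primer)
        hits = []
        for p in range(len(seq) - m + 1):
            win = seq[p : p + m]
            mm = sum(a != b for a, b in zip(win, primer))
            if mm > max_mm:
                continue
            if tail == "right" and win[-3:] != primer[-3:]:
                continue
            if tail == "left" and win[:3] != primer[:3]:
                continue
            hits.append(p)
        return hits

    out = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        for a, b, strand in (
            (fwd, rev, "+"),
            (rev, fwd, "-"),
        ):
            for i in sites(seq, a, "right"):
                for j in sites(seq, revcomp(b), "left"):
                    if j >= i + len(a) and j + len(b) - i <= max_product:
                        out.add((chrom, i + 1, j + len(b), strand))
    return out


def pic_double_sum(p) -> float:
    """PIC via the textbook double sum 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    s = 1.0 - sum(x * x for x in p)
    for i, j in itertools.combinations(range(len(p)), 2):
        s -= 2.0 * p[i] ** 2 * p[j] ** 2
    return s


def pi_genotype_enumeration(p) -> float:
    """PI as the sum over unordered HWE genotypes g of P(g)^2."""
    total = 0.0
    for i in range(len(p)):
        total += (p[i] ** 2) ** 2
        for j in range(i + 1, len(p)):
            total += (2 * p[i] * p[j]) ** 2
    return total
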
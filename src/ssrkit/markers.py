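"""Primer-pair screening and in-silico PCR (e-PCR).

Candidate SSR primer pairs are screened against the usual design
criteria (length 18-27 bp, GC 40-60%, Tm 55-65 degC with < 3 degC
difference between mates, product 100-280 bp), then virtually amplified
against a genome.  Markers are classified from the predicted amplicon
count: one predicted locus -> monomorphic, several -> polymorphic.

Melting temperatures default to nearest-neighbor thermodynamics with
the SantaLucia (1998) unified parameter set at 50 mM monovalent salt
and 250 nM total oligo; the Wallace 2/4 rule is available for
hand-checkable arithmetic.  An M13 tail, when flagged, is treated as
synthesis metadata: it is stripped before any criterion or e-PCR
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .miner import reverse_complement

__all__ = [
    "M13_TAIL",
    "PrimerPair",
    "DesignCriteria",
    "AmpliconPrediction",
    "gc_content",
    "melting_temp",
    "check_primer_pair",
    "insilico_pcr",
    "classify_marker",
]

M13_TAIL = "TGTAAAACGACGGCCAGT"

# SantaLucia (1998) unified NN parameters: dH kcal/mol, dS cal/(mol K)
_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT_GC = (0.1, -2.8)  # terminal G or C
_INIT_AT = (2.3, 4.1)  # terminal A or T
_R_GAS = 1.987  # cal/(mol K)


def _validate_seq(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if not s:
        raise ValueError(f"empty {what}")
    if set(s) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {what}: {seq!r}")
    return s


def gc_content(seq: str) -> float:
    """GC percentage of a nucleotide string, on a 0-100 scale."""
    s = _validate_seq(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def melting_temp(
    seq: str,
    method: str = "nn",
    na_mm: float = 50.0,
    oligo_nm: float = 250.0,
) -> float:
    """Melting temperature in degrees Celsius.

    ``wallace``: the 2(A+T) + 4(G+C) rule.  ``nn``: SantaLucia (1998)
    unified nearest-neighbor thermodynamics with the 0.368*(N-1)*ln[Na+]
    entropic salt correction and a symmetry correction for
    self-complementary oligos; *na_mm* is monovalent cation in mM and
    *oligo_nm* total strand concentration in nM.
    """
    s = _validate_seq(seq, "primer")
    if len(s) < 8:
        raise ValueError(f"primer too short for Tm ({len(s)} nt)")
    if method == "wallace":
        at = s.count("A") + s.count("T")
        return float(2 * at + 4 * (len(s) - at))
    if method != "nn":
        raise ValueError(f"unknown Tm method {method!r}")
    dh = 0.0
    ds = 0.0
    for base in (s[0], s[-1]):
        inc = _INIT_GC if base in "GC" else _INIT_AT
        dh += inc[0]
        ds += inc[1]
    for i in range(len(s) - 1):
        pair = s[i : i + 2]
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]
    selfcomp = s == reverse_complement(s)
    if selfcomp:
        ds += -1.4
    ds += 0.368 * (len(s) - 1) * math.log(na_mm / 1000.0)
    ct = oligo_nm * 1e-9
    k = ct if selfcomp else ct / 4.0
    return 1000.0 * dh / (ds + _R_GAS * math.log(k)) - 273.15


@dataclass
class PrimerPair:
    """A named forward/reverse primer pair (both 5'->3')."""

    name: str
    forward: str
    reverse: str
    dye: str | None = None
    m13_tail: bool = False

    def core(self) -> tuple[str, str]:
        """Primer sequences with any M13 tail stripped."""
        f, r = self.forward.upper(), self.reverse.upper()
        if self.m13_tail:
            if f.startswith(M13_TAIL):
                f = f[len(M13_TAIL):]
            if r.startswith(M13_TAIL):
                r = r[len(M13_TAIL):]
        return f, r


@dataclass
class DesignCriteria:
    length_range: tuple[int, int] = (18, 27)
    gc_range: tuple[float, float] = (40.0, 60.0)
    tm_range: tuple[float, float] = (55.0, 65.0)
    max_tm_diff: float = 3.0
    product_range: tuple[int, int] = (100, 280)


def check_primer_pair(
    pair: PrimerPair,
    criteria: DesignCriteria | None = None,
    product_size: int | None = None,
    tm_method: str = "nn",
) -> tuple[bool, list[str]]:
    """Screen a primer pair against design criteria.

    Returns ``(passed, reasons)`` where *reasons* lists every violated
    criterion among ``length``, ``gc``, ``tm``, ``tm_diff`` and
    ``product_size`` (checked only when *product_size* is given).
    M13 tails are excluded from every computation.
    """
    if criteria is None:
        criteria = DesignCriteria()
    f, r = pair.core()
    reasons: list[str] = []
    lo, hi = criteria.length_range
    if not (lo <= len(f) <= hi and lo <= len(r) <= hi):
        reasons.append("length")
    glo, ghi = criteria.gc_range
    if not all(glo <= gc_content(p) <= ghi for p in (f, r)):
        reasons.append("gc")
    tms = [melting_temp(p, method=tm_method) for p in (f, r)]
    tlo, thi = criteria.tm_range
    if not all(tlo <= t <= thi for t in tms):
        reasons.append("tm")
    if abs(tms[0] - tms[1]) >= criteria.max_tm_diff:
        reasons.append("tm_diff")
    if product_size is not None:
        plo, phi = criteria.product_range
        if not plo <= product_size <= phi:
            reasons.append("product_size")
    return (not reasons, reasons)


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product (outer primer-to-primer span, 1-based)."""

    primer: str
    chrom: str
    start: int
    end: int
    strand: str  # strand carrying the forward-primer hit

    @property
    def product_size(self) -> int:
        return self.end - self.start + 1


def _hits(seq: str, pattern: str, max_mm: int, exact_tail: str) -> list[int]:
    """0-based start positions where *pattern* matches *seq* with at most
    *max_mm* mismatches; the 3 bases at the primer's 3' end (``left`` or
    ``right`` end of the pattern per *exact_tail*) must match exactly."""
    m = len(pattern)
    n = len(seq)
    out = []
    if max_mm == 0:
        i = seq.find(pattern)
        while i != -1:
            out.append(i)
            i = seq.find(pattern, i + 1)
        return out
    seed = pattern[:3] if exact_tail == "left" else pattern[-3:]
    off = 0 if exact_tail == "left" else m - 3
    i = seq.find(seed)
    while i != -1:
        p = i - off
        if 0 <= p <= n - m:
            window = seq[p : p + m]
            mm = sum(a != b for a, b in zip(window, pattern))
            if mm <= max_mm:
                out.append(p)
        i = seq.find(seed, i + 1)
    return sorted(set(out))


def insilico_pcr(
    genome: dict[str, str],
    pair: PrimerPair,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list[AmpliconPrediction]:
    """Virtually amplify a primer pair against a genome (e-PCR).

    Reports every site where the two primers bind opposite strands in
    convergent, non-overlapping orientation within *max_product* bp,
    each with at most *max_mismatch* mismatches and an exact match over
    the 3 bases at the primer's 3' terminus.  Predictions are
    deduplicated and sorted by (chrom, start).
    """
    f, r = pair.core()
    if min(len(f), len(r)) < 12:
        raise ValueError("primers must be >= 12 nt for e-PCR")
    preds: set[AmpliconPrediction] = set()
    for chrom, raw in genome.items():
        seq = raw.upper()
        # forward primer on plus strand, reverse binds downstream
        plus_f = _hits(seq, f, max_mismatch, "right")
        minus_r = _hits(seq, reverse_complement(r), max_mismatch, "left")
        for i in plus_f:
            for j in minus_r:
                if j < i + len(f):
                    continue
                end = j + len(r)
                if end - i <= max_product:
                    preds.add(
                        AmpliconPrediction(pair.name, chrom, i + 1, end, "+")
                    )
        # forward primer on minus strand, reverse on plus upstream
        plus_r = _hits(seq, r, max_mismatch, "right")
        minus_f = _hits(seq, reverse_complement(f), max_mismatch, "left")
        for i in plus_r:
            for j in minus_f:
                if j < i + len(r):
                    continue
                end = j + len(f)
                if end - i <= max_product:
                    preds.add(
                        AmpliconPrediction(pair.name, chrom, i + 1, end, "-")
                    )
    return sorted(preds, key=lambda a: (a.chrom, a.start, a.end, a.strand))


def classify_marker(predictions: list[AmpliconPrediction]) -> str | None:
    """``None`` for no predicted product, ``monomorphic`` for a single
    predicted locus, ``polymorphic`` for multiple loci."""
    if not predictions:
        return None
    return "monomorphic" if len(predictions) == 1 else "polymorphic"
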
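"""Detection and classification of perfect microsatellites (SSRs).

A simple sequence repeat (SSR) is a tandem repetition of a 1-6 bp DNA
unit.  This module finds every *maximal perfect* tandem run whose
full-unit repeat count reaches a per-unit-length threshold (the common
genome-survey defaults: mono >= 10, di >= 6, tri/tetra/penta/hexa >= 5),
groups motifs into canonical classes under cyclic rotation and reverse
complementation (so CT and GA both report as AG), annotates compound
loci closer than a spacing cutoff, and aggregates Table-style genome
summaries and windowed density tracks.

Coordinates are 1-based inclusive throughout; BED export (``ssrkit.io``)
converts to 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRLocus",
    "SearchParams",
    "GenomeSummary",
    "reverse_complement",
    "is_primitive",
    "canonical_motif",
    "enumerate_motif_classes",
    "classify_length",
    "find_ssrs",
    "annotate_compound",
    "summarize_genome",
    "window_density",
]

#: minimum number of full repeat units per unit length (1..6)
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGTN")
_UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not itself a tandem repetition of a shorter unit.

    E.g. ``ACA`` is primitive, ``ATAT`` is not (= ``AT`` x 2).
    """
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Class representative of *motif*: the lexicographically smallest
    string among all cyclic rotations of the motif and of its reverse
    complement.

    This reproduces the conventional complementary-pair representatives
    (A/T -> A, AG/CT -> AG, AAG/CTT -> AAG, AGAT/ATCT -> AGAT) and is
    idempotent.

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 bp, contains non-ACGT
        characters, or is not primitive.
    """
    m = motif.upper()
    if not 1 <= len(m) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(m) - set("ACGT"):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if not is_primitive(m):
        raise ValueError(f"motif is not primitive: {motif!r}")
    rc = reverse_complement(m)
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


@lru_cache(maxsize=None)
def enumerate_motif_classes(unit_length: int) -> int:
    """Number of distinct canonical motif classes among all primitive
    motifs of a given unit length.

    Brute-force enumeration of all ``4**k`` strings, dropping
    non-primitive ones and grouping by :func:`canonical_motif`.
    Yields 2, 4, 10, 33, 102, 350 for k = 1..6.
    """
    if not 1 <= unit_length <= 6:
        raise ValueError(f"unit_length must be 1-6, got {unit_length}")
    classes = set()
    for tup in itertools.product("ACGT", repeat=unit_length):
        m = "".join(tup)
        if is_primitive(m):
            classes.add(canonical_motif(m))
    return len(classes)


def classify_length(length_bp: int) -> str:
    """Length class of an SSR: ``III`` (<20 nt), ``II`` (20-30 nt,
    inclusive), or ``I`` (>30 nt)."""
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    if length_bp < 20:
        return "III"
    if length_bp <= 30:
        return "II"
    return "I"


@dataclass
class SSRLocus:
    """One detected perfect tandem repeat (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    motif: str
    unit_length: int
    n_repeats: int
    canonical: str = ""
    length_class: str = ""
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not self.canonical:
            self.canonical = canonical_motif(self.motif)
        if not self.length_class:
            self.length_class = classify_length(self.length_bp)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class SearchParams:
    """SSR search settings.

    ``min_repeats`` maps unit length (1..6) to the minimum number of
    full repeat units; ``compound_gap_bp`` is the maximum spacing at
    which adjacent loci are flagged as a compound; ``ambiguous_ok``
    controls whether N bases are tolerated (terminating runs) or
    rejected outright.
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_gap_bp: int = 100
    ambiguous_ok: bool = True

    def __post_init__(self) -> None:
        for k, v in self.min_repeats.items():
            if k not in range(1, 7) or v < 1:
                raise ValueError(f"invalid threshold {k}: {v}")
        if self.compound_gap_bp < 0:
            raise ValueError("compound_gap_bp must be >= 0")


def find_ssrs(
    sequence: str, chrom: str = "chr1", params: SearchParams | None = None
) -> list[SSRLocus]:
    """Find every maximal perfect SSR in *sequence*.

    A locus covers only full repeat units (a trailing partial unit is
    excluded); its motif is primitive; its full-unit count meets the
    threshold for its unit length; it never spans an ambiguous base.
    A locus whose interval lies entirely inside another locus's interval
    is suppressed (shorter-unit interpretation wins on an exact tie), so
    a run is never double-reported at a multiple of its true period.
    Lowercase input is accepted and upper-cased.

    Returns loci sorted by start position.
    """
    if params is None:
        params = SearchParams()
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad or (not params.ambiguous_ok and "N" in seq):
        probe = bad if bad else {"N"}
        pos = min(i for i, c in enumerate(seq) if c in probe)
        raise ValueError(
            f"non-nucleotide character {seq[pos]!r} at position {pos + 1} "
            f"in {chrom}"
        )
    n = len(seq)
    found: list[SSRLocus] = []
    for k in range(1, 7):
        thr = params.min_repeats.get(k)
        if thr is None:
            continue
        i = 0
        limit = n - k * thr
        while i <= limit:
            motif = seq[i : i + k]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            j = i + k
            while j + k <= n and seq[j : j + k] == motif:
                j += k
            r = (j - i) // k
            if r >= thr:
                found.append(
                    SSRLocus(chrom, i + 1, i + r * k, motif, k, r)
                )
                i += r * k
            else:
                i += 1
    # suppress loci nested inside another locus (ties -> smaller unit)
    found.sort(key=lambda l: (l.start, -l.end, l.unit_length))
    kept: list[SSRLocus] = []
    cover_end = 0
    for loc in found:
        if loc.end <= cover_end:
            continue
        kept.append(loc)
        cover_end = max(cover_end, loc.end)
    kept.sort(key=lambda l: l.start)
    return kept


def annotate_compound(
    loci: Sequence[SSRLocus], gap: int = 100
) -> list[SSRLocus]:
    """Tag runs of nearby loci with a shared ``compound_id``.

    Consecutive loci on one chromosome whose spacing
    (``next.start - prev.end - 1``) is <= *gap* form a compound group
    (transitively).  Counts of individual loci are unchanged; singleton
    groups keep ``compound_id=None``.
    """
    out: list[SSRLocus] = []
    by_chrom: dict[str, list[SSRLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.start)
        cluster: list[SSRLocus] = []
        n_comp = 0

        def flush() -> int:
            nonlocal n_comp
            if len(cluster) >= 2:
                n_comp += 1
                cid = f"{chrom}.c{n_comp}"
                out.extend(replace(l, compound_id=cid) for l in cluster)
            else:
                out.extend(replace(l, compound_id=None) for l in cluster)
            return 0

        for loc in group:
            if cluster and loc.start - cluster[-1].end - 1 <= gap:
                cluster.append(loc)
            else:
                flush()
                cluster = [loc]
        flush()
    out.sort(key=lambda l: (l.chrom, l.start))
    return out


@dataclass
class GenomeSummary:
    """Genome-wide SSR aggregate in the style of a survey table."""

    examined_bp: int
    total_ssrs: int
    total_ssr_bp: int
    coverage_pct: float
    relative_abundance: float  # loci / Mb
    relative_density: float  # bp / Mb
    mean_ssr_length_bp: float
    per_unit_length: pd.DataFrame  # indexed by unit_length 1..6

    def to_frame(self) -> pd.DataFrame:
        return self.per_unit_length.copy()


def _per_mb(x: float, examined_bp: int) -> float:
    return x / (examined_bp / 1e6)


def summarize_genome(
    loci: Sequence[SSRLocus], examined_bp: int
) -> GenomeSummary:
    """Aggregate mined loci into a :class:`GenomeSummary`.

    Relative abundance is loci/Mb, relative density bp/Mb, coverage the
    percentage of examined sequence inside perfect SSRs.  An empty locus
    list yields an all-zero summary so that pipelines compose.
    """
    if examined_bp <= 0:
        raise ValueError("examined_bp must be > 0")
    rows = []
    for k in range(1, 7):
        sub = [l for l in loci if l.unit_length == k]
        count = len(sub)
        total_len = sum(l.length_bp for l in sub)
        reps = [l.n_repeats for l in sub]
        rows.append(
            {
                "unit_length": k,
                "type": _UNIT_NAMES[k],
                "count": count,
                "total_length_bp": total_len,
                "mean_repeats": float(np.mean(reps)) if reps else 0.0,
                "min_repeats": min(reps) if reps else 0,
                "max_repeats": max(reps) if reps else 0,
                "relative_abundance": _per_mb(count, examined_bp),
                "relative_density": _per_mb(total_len, examined_bp),
            }
        )
    per = pd.DataFrame(rows).set_index("unit_length")
    total = int(per["count"].sum())
    total_bp = int(per["total_length_bp"].sum())
    per["pct_of_total"] = (
        100.0 * per["count"] / total if total else 0.0
    )
    return GenomeSummary(
        examined_bp=examined_bp,
        total_ssrs=total,
        total_ssr_bp=total_bp,
        coverage_pct=100.0 * total_bp / examined_bp,
        relative_abundance=_per_mb(total, examined_bp),
        relative_density=_per_mb(total_bp, examined_bp),
        mean_ssr_length_bp=total_bp / total if total else 0.0,
        per_unit_length=per,
    )


def window_density(
    loci: Iterable[SSRLocus],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 100_000,
) -> dict[str, np.ndarray]:
    """Count loci per non-overlapping window along each chromosome.

    Window i (1-based) covers ``[(i-1)*w + 1, i*w]``; the last window is
    truncated at the chromosome end.  A locus is counted in the window
    containing its start.  The counts of each vector sum to the number
    of loci on that chromosome.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out = {
        c: np.zeros(max(1, -(-length // window_bp)), dtype=int)
        for c, length in chrom_lengths.items()
    }
    for loc in loci:
        if loc.chrom not in chrom_lengths:
            raise ValueError(f"locus on unknown chromosome: {loc}")
        if loc.end > chrom_lengths[loc.chrom] or loc.start < 1:
            raise ValueError(
                f"locus outside chromosome bounds: {loc.chrom}:"
                f"{loc.start}-{loc.end}"
            )
        out[loc.chrom][(loc.start - 1) // window_bp] += 1
    return out
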
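"""DNA fingerprint codes from SSR fragment-size genotypes.

Two encodings are supported:

* ``zygosity`` - one digit per (individual, locus): 9 for a missing
  call, 0 for a heterozygote (two distinct sizes in the diploid view),
  1 for a homozygote.
* ``bins`` - per locus, fragment sizes are grouped into 10-bp bins
  numbered 1-9 starting at the locus's bin origin (by default the
  minimum observed size); sizes beyond the ninth bin fall into bin 9
  and missing slots are 0.  Each locus contributes a fixed-width group
  of four digits (up to four recorded alleles, ascending, zero-padded).

The module also checks whether a code set distinguishes every
individual and selects minimal discriminating marker subsets by greedy
or exhaustive search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .genotypes import GenotypeTable

__all__ = [
    "BinScheme",
    "FingerprintCode",
    "encode_zygosity",
    "encode_bins",
    "check_distinguishable",
    "min_discriminating_set",
]

BIN_WIDTH = 10
GROUP_WIDTH = 4  # allele slots per locus under the bins scheme


@dataclass(frozen=True)
class FingerprintCode:
    individual: str
    scheme: str  # "zygosity" | "bins"
    groups: tuple[str, ...]  # one digit group per locus, table order

    @property
    def code(self) -> str:
        return "".join(self.groups)


@dataclass
class BinScheme:
    """Per-locus bin origins for the 10-bp grouping.

    ``bin(size) = min(9, 1 + (size - start) // 10)``; the start of each
    locus defaults to its minimum observed fragment size.
    """

    starts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "BinScheme":
        starts = {}
        for loc in table.loci:
            sizes = [
                s for ind in table.individuals for s in table.alleles(ind, loc)
            ]
            if not sizes:
                raise ValueError(f"locus {loc!r} has no recorded sizes")
            starts[loc] = min(sizes)
        return cls(starts)

    def digit(self, locus: str, size: int) -> int:
        start = self.starts[locus]
        if size < start:
            raise ValueError(
                f"size {size} below bin origin {start} at locus {locus!r}"
            )
        return min(9, 1 + (size - start) // BIN_WIDTH)

    def legend(self) -> list[tuple[str, int, int]]:
        """(locus, start, last in-range size) rows for reporting."""
        return [
            (loc, s, s + 9 * BIN_WIDTH - 1) for loc, s in self.starts.items()
        ]


def encode_zygosity(table: GenotypeTable) -> list[FingerprintCode]:
    """One digit per locus: missing 9, heterozygous 0, homozygous 1."""
    codes = []
    for ind in table.individuals:
        groups = []
        for loc in table.loci:
            dip = table.diploid(ind, loc)
            if dip is None:
                groups.append("9")
            elif dip[0] == dip[1]:
                groups.append("1")
            else:
                groups.append("0")
        codes.append(FingerprintCode(ind, "zygosity", tuple(groups)))
    return codes


def encode_bins(
    table: GenotypeTable, scheme: BinScheme | None = None
) -> list[FingerprintCode]:
    """Four bin digits per locus (ascending size order, zero-padded);
    a fully missing cell encodes as ``0000``."""
    if scheme is None:
        scheme = BinScheme.from_table(table)
    codes = []
    for ind in table.individuals:
        groups = []
        for loc in table.loci:
            sizes = sorted(table.alleles(ind, loc))
            digits = [str(scheme.digit(loc, s)) for s in sizes]
            digits += ["0"] * (GROUP_WIDTH - len(digits))
            groups.append("".join(digits))
        codes.append(FingerprintCode(ind, "bins", tuple(groups)))
    return codes


def check_distinguishable(
    codes: list[FingerprintCode],
) -> list[list[str]]:
    """Groups of individuals sharing an identical full code; an empty
    result means every individual is distinguishable."""
    by_code: dict[str, list[str]] = {}
    for c in codes:
        by_code.setdefault(c.code, []).append(c.individual)
    return [grp for grp in by_code.values() if len(grp) > 1]


def _encoder(table: GenotypeTable, scheme):
    if scheme == "zygosity":
        return encode_zygosity(table)
    if scheme == "bins" or isinstance(scheme, BinScheme):
        bs = scheme if isinstance(scheme, BinScheme) else None
        return encode_bins(table, bs)
    raise ValueError(f"unknown scheme {scheme!r}")


def _groups_by_locus(table: GenotypeTable, scheme) -> dict[str, list[str]]:
    codes = _encoder(table, scheme)
    return {
        loc: [c.groups[j] for c in codes]
        for j, loc in enumerate(table.loci)
    }


def _discriminates(per_locus, loci, n: int) -> bool:
    seen = {tuple(per_locus[l][i] for l in loci) for i in range(n)}
    return len(seen) == n


def min_discriminating_set(
    table: GenotypeTable,
    scheme="bins",
    strategy: str = "greedy",
) -> list[str]:
    """Smallest (exhaustive) or small (greedy) locus subset whose codes
    distinguish every individual.

    Greedy iteratively adds the locus that minimizes the number of
    still-identical pairs (ties by table locus order); exhaustive scans
    subset sizes breadth-first and is limited to panels of <= 12 loci.
    Raises if even the full panel leaves duplicate groups, listing them.
    """
    n = table.n_individuals()
    per_locus = _groups_by_locus(table, scheme)
    full = table.loci
    if not _discriminates(per_locus, full, n):
        dups = check_distinguishable(_encoder(table, scheme))
        raise ValueError(f"full panel cannot distinguish: {dups}")
    if strategy == "exhaustive":
        if len(full) > 12:
            raise ValueError("exhaustive search limited to <= 12 loci")
        for size in range(1, len(full) + 1):
            for combo in itertools.combinations(full, size):
                if _discriminates(per_locus, combo, n):
                    return list(combo)
    if strategy != "greedy":
        raise ValueError(f"unknown strategy {strategy!r}")
    chosen: list[str] = []
    keys = [() for _ in range(n)]
    while True:
        groups: dict[tuple, int] = {}
        for k in keys:
            groups[k] = groups.get(k, 0) + 1
        unresolved = sum(c * (c - 1) // 2 for c in groups.values())
        if unresolved == 0:
            return chosen
        best_loc, best_score = None, None
        for loc in full:
            if loc in chosen:
                continue
            trial: dict[tuple, int] = {}
            for i in range(n):
                k = keys[i] + (per_locus[loc][i],)
                trial[k] = trial.get(k, 0) + 1
            score = sum(c * (c - 1) // 2 for c in trial.values())
            if best_score is None or score < best_score:
                best_loc, best_score = loc, score
        chosen.append(best_loc)
        keys = [keys[i] + (per_locus[best_loc][i],) for i in range(n)]
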
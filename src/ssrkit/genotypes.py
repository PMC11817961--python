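"""Genotype tables of per-individual, per-locus allele fragment sizes.

Capillary-electrophoresis SSR genotyping reports fragment sizes in bp;
for a polyploid up to four sizes may be recorded per individual and
locus.  Diversity and identity statistics operate on a *diploid view*
(the first two recorded sizes, a single size meaning homozygous);
fingerprint bin coding uses all recorded sizes.  A missing call is an
empty size list.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

__all__ = ["GenotypeTable"]


class GenotypeTable:
    """Individuals x loci table of allele fragment sizes (bp).

    Parameters
    ----------
    individuals, loci
        Ordered, unique identifiers.
    cells
        Mapping ``(individual, locus) -> sequence of 0-4 positive
        integer sizes``.  Absent keys and empty sequences both mean
        missing.
    """

    MAX_ALLELES = 4

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        cells: Mapping[tuple[str, str], Sequence[int]],
    ) -> None:
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus ids")
        self.individuals = list(individuals)
        self.loci = list(loci)
        self._cells: dict[tuple[str, str], tuple[int, ...]] = {}
        ind_set, loc_set = set(self.individuals), set(self.loci)
        for (ind, loc), sizes in cells.items():
            if ind not in ind_set or loc not in loc_set:
                raise ValueError(f"cell ({ind!r}, {loc!r}) outside table")
            t = tuple(int(s) for s in sizes)
            if len(t) > self.MAX_ALLELES:
                raise ValueError(
                    f"more than {self.MAX_ALLELES} sizes at ({ind}, {loc})"
                )
            if any(s <= 0 for s in t):
                raise ValueError(f"non-positive size at ({ind}, {loc}): {t}")
            if t:
                self._cells[(ind, loc)] = t

    # -- access ---------------------------------------------------------
    def alleles(self, individual: str, locus: str) -> tuple[int, ...]:
        """All recorded sizes for a cell (empty tuple if missing)."""
        return self._cells.get((individual, locus), ())

    def diploid(self, individual: str, locus: str) -> tuple[int, int] | None:
        """Two-allele view of a cell: the first two recorded sizes, a
        single size duplicated, or ``None`` if missing."""
        t = self.alleles(individual, locus)
        if not t:
            return None
        if len(t) == 1:
            return (t[0], t[0])
        return (t[0], t[1])

    def is_missing(self, individual: str, locus: str) -> bool:
        return (individual, locus) not in self._cells

    def n_individuals(self) -> int:
        return len(self.individuals)

    def n_loci(self) -> int:
        return len(self.loci)

    # -- manipulation ---------------------------------------------------
    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        missing = set(loci) - set(self.loci)
        if missing:
            raise KeyError(f"unknown loci: {sorted(missing)}")
        cells = {
            (i, l): self._cells[(i, l)]
            for i in self.individuals
            for l in loci
            if (i, l) in self._cells
        }
        return GenotypeTable(self.individuals, list(loci), cells)

    def to_records(self) -> Iterator[tuple[str, str, tuple[int, ...]]]:
        for ind in self.individuals:
            for loc in self.loci:
                yield ind, loc, self.alleles(ind, loc)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, Sequence[int]]]
    ) -> "GenotypeTable":
        """Build a table from (individual, locus, sizes) rows, keeping
        first-appearance ordering of individuals and loci."""
        individuals: list[str] = []
        loci: list[str] = []
        cells: dict[tuple[str, str], Sequence[int]] = {}
        for ind, loc, sizes in records:
            if ind not in individuals:
                individuals.append(ind)
            if loc not in loci:
                loci.append(loc)
            cells[(ind, loc)] = sizes
        return cls(individuals, loci, cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self._cells == other._cells
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({len(self.individuals)} individuals x "
            f"{len(self.loci)} loci)"
        )
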
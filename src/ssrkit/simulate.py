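"""Synthetic genomes with planted SSR truth and structured genotype
panels.

``generate_genome`` emulates a chromosome-scale plant assembly at desk
scale: i.i.d. background sequence at a chosen GC level with perfect
SSRs planted at known motif/length/position, optionally biased toward
chromosome ends (a pattern typical of grass genomes).  Background
windows that happen to contain an above-threshold repeat are redrawn so
the truth table stays exact and the miner's planted-genome recall and
precision are both testable at 1.0.

``generate_panel`` emulates a fragment-size genotyping cohort: K
ancestral clusters carry Dirichlet allele-frequency profiles over a
size ladder (base size + unit-length steps), individuals carry
Dirichlet(alpha) admixture proportions, and each of the two allele
copies per locus is an independent draw from the individual's mixture.
Missing calls are imposed completely at random.  Coordinates either
follow ancestry (cluster centers plus noise, giving isolation by
distance) or are uniform.  Defaults mirror a 105-accession, 20-locus,
4-cluster cohort with weak spatial signal.

All generators take explicit integer seeds and never touch global
random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .miner import (
    DEFAULT_MIN_REPEATS,
    SSRLocus,
    SearchParams,
    find_ssrs,
    is_primitive,
)

__all__ = [
    "GenomeParams",
    "PlantedGenome",
    "generate_genome",
    "PanelParams",
    "SimulatedPanel",
    "generate_panel",
]

# motif-class mix and mean repeat counts loosely shaped like a large
# grass genome survey (mono/di/tri dominate; tetra-hexa are rare)
_DEFAULT_UNIT_WEIGHTS = {1: 0.433, 2: 0.351, 3: 0.202, 4: 0.009,
                         5: 0.002, 6: 0.003}
_DEFAULT_MEAN_REPEATS = {1: 13.1, 2: 9.3, 3: 6.1, 4: 5.8, 5: 6.1, 6: 5.7}


@dataclass
class GenomeParams:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000}
    )
    ssr_rate_per_mb: float = 124.0
    unit_weights: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_UNIT_WEIGHTS)
    )
    mean_repeats: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEAN_REPEATS)
    )
    end_bias: float = 1.0  # 0 = uniform; >0 concentrates SSRs near ends
    gc: float = 0.46
    min_spacing_bp: int = 150  # between planted loci (> compound gap)
    max_repeats: int = 60


@dataclass
class PlantedGenome:
    sequences: dict[str, str]
    truth: list[SSRLocus]
    params: GenomeParams
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": l.chrom,
                    "start": l.start,
                    "end": l.end,
                    "motif": l.motif,
                    "unit_length": l.unit_length,
                    "n_repeats": l.n_repeats,
                }
                for l in self.truth
            ]
        )


def _random_primitive_motif(rng: np.random.Generator, k: int) -> str:
    while True:
        m = "".join(rng.choice(list("ACGT"), size=k))
        if is_primitive(m):
            return m


def _draw_positions(rng, length, count, spacing, bias):
    """Sample *count* start positions with pairwise gaps > spacing and
    sampling density proportional to 1 + bias * edge proximity."""
    taken: list[int] = []
    for _ in range(count * 200):
        if len(taken) == count:
            break
        x = int(rng.integers(1, length))
        prox = 1.0 - min(x, length - x) / (length / 2.0)
        if rng.random() > (1.0 + bias * prox) / (1.0 + max(bias, 0.0)):
            continue
        if all(abs(x - t) > spacing for t in taken):
            taken.append(x)
    if len(taken) < count:
        raise ValueError(
            f"cannot place {count} SSRs with spacing {spacing} "
            f"in {length} bp"
        )
    return sorted(taken)


def generate_genome(
    params: GenomeParams | None = None, seed: int = 0
) -> PlantedGenome:
    """Generate chromosomes with planted perfect SSRs and an exact truth
    table.

    Planted loci always satisfy the default mining thresholds and are
    separated by more than ``min_spacing_bp``.  After planting, the
    background is rescanned and any accidental above-threshold repeat
    outside the truth set is redrawn (rejection loop, bounded); this
    keeps miner recall and precision at exactly 1.0 on the output.
    """
    if params is None:
        params = GenomeParams()
    for c, length in params.chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"chromosome {c} shorter than 10 kb")
    if params.ssr_rate_per_mb < 0:
        raise ValueError("ssr_rate_per_mb must be >= 0")
    rng = np.random.default_rng(seed)
    gc = params.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    units = sorted(params.unit_weights)
    w = np.array([params.unit_weights[u] for u in units], dtype=float)
    w /= w.sum()
    sequences: dict[str, str] = {}
    truth: list[SSRLocus] = []
    search = SearchParams()
    for chrom, length in params.chrom_lengths.items():
        count = int(round(params.ssr_rate_per_mb * length / 1e6))
        seq = rng.choice(bases, size=length, p=probs)
        placed: list[SSRLocus] = []
        if count:
            # budget for the longest possible planted locus
            max_len = 6 * params.max_repeats
            starts = _draw_positions(
                rng,
                length - max_len - 1,
                count,
                params.min_spacing_bp + max_len,
                params.end_bias,
            )
            for x in starts:
                k = int(rng.choice(units, p=w))
                thr = DEFAULT_MIN_REPEATS[k]
                mean_extra = max(params.mean_repeats[k] - thr, 0.1)
                r = thr + int(rng.geometric(1.0 / (1.0 + mean_extra)) - 1)
                r = min(r, params.max_repeats)
                motif = _random_primitive_motif(rng, k)
                run = (motif * r)
                seq[x - 1 : x - 1 + len(run)] = list(run)
                placed.append(SSRLocus(chrom, x, x + len(run) - 1, motif, k, r))
        # rejection loop: redraw background windows that mine as SSRs
        truth_keys = {(l.start, l.end, l.motif) for l in placed}
        planted_mask = np.zeros(length, dtype=bool)
        for l in placed:
            planted_mask[l.start - 1 : l.end] = True
        for _ in range(50):
            mined = find_ssrs("".join(seq), chrom, search)
            stray = [
                m
                for m in mined
                if (m.start, m.end, m.motif) not in truth_keys
            ]
            if not stray:
                break
            for m in stray:
                lo = max(0, m.start - 2)
                hi = min(length, m.end + 1)
                idx = np.arange(lo, hi)
                idx = idx[~planted_mask[idx]]
                seq[idx] = rng.choice(bases, size=len(idx), p=probs)
        else:
            raise RuntimeError(
                "could not clear accidental background SSRs within the "
                "iteration cap"
            )
        sequences[chrom] = "".join(seq)
        truth.extend(placed)
    truth.sort(key=lambda l: (l.chrom, l.start))
    return PlantedGenome(sequences, truth, params, seed)


@dataclass
class PanelParams:
    n: int = 105
    L: int = 20
    K: int = 4
    alpha: float = 0.2  # Dirichlet concentration for admixture Q
    freq_conc: float = 0.5  # Dirichlet concentration for cluster freqs
    n_alleles: int = 12
    base_size: int = 100
    step_bp: int = 2  # allele ladder step (dinucleotide unit)
    missing_rate: float = 0.05
    isolation_by_distance: bool = True
    coord_box: tuple[float, float, float, float] = (38.0, 43.0, 108.0, 116.0)
    coord_noise_deg: float = 0.5


@dataclass
class SimulatedPanel:
    table: GenotypeTable
    true_q: pd.DataFrame
    true_freqs: dict[str, pd.DataFrame]
    coords: pd.DataFrame
    params: PanelParams
    seed: int


def generate_panel(
    params: PanelParams | None = None, seed: int = 0
) -> SimulatedPanel:
    """Simulate a structured diploid fragment-size genotype panel.

    Per cluster and locus, allele frequencies are Dirichlet over a size
    ladder ``base + step * j``; per individual, ancestry Q is
    Dirichlet(alpha); the two allele copies at each locus are
    independent draws from the Q-mixture.  Missing cells are MCAR at
    ``missing_rate``.  With isolation by distance on, an individual
    sits at the Q-weighted mix of its cluster centers plus noise.
    """
    if params is None:
        params = PanelParams()
    if not (params.n >= params.K >= 1 and params.L >= 1):
        raise ValueError("require n >= K >= 1 and L >= 1")
    if params.alpha <= 0 or params.freq_conc <= 0:
        raise ValueError("Dirichlet concentrations must be > 0")
    if not 0 <= params.missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    inds = [f"S{i + 1:03d}" for i in range(params.n)]
    loci = [f"L{j + 1:02d}" for j in range(params.L)]
    ladder = [
        params.base_size + params.step_bp * j for j in range(params.n_alleles)
    ]
    freqs = {
        loc: pd.DataFrame(
            rng.dirichlet(
                np.full(params.n_alleles, params.freq_conc), size=params.K
            ),
            index=[f"K{k + 1}" for k in range(params.K)],
            columns=ladder,
        )
        for loc in loci
    }
    q = rng.dirichlet(np.full(params.K, params.alpha), size=params.n)
    cells: dict[tuple[str, str], tuple[int, ...]] = {}
    for i, ind in enumerate(inds):
        for loc in loci:
            if rng.random() < params.missing_rate:
                continue
            copies = []
            for _ in range(2):
                k = rng.choice(params.K, p=q[i])
                a = rng.choice(params.n_alleles, p=freqs[loc].iloc[k].values)
                copies.append(ladder[a])
            cells[(ind, loc)] = tuple(copies)
    table = GenotypeTable(inds, loci, cells)
    lat0, lat1, lon0, lon1 = params.coord_box
    if params.isolation_by_distance:
        centers = np.column_stack(
            [
                rng.uniform(lat0, lat1, size=params.K),
                rng.uniform(lon0, lon1, size=params.K),
            ]
        )
        xy = q @ centers + rng.normal(
            0.0, params.coord_noise_deg, size=(params.n, 2)
        )
    else:
        xy = np.column_stack(
            [
                rng.uniform(lat0, lat1, size=params.n),
                rng.uniform(lon0, lon1, size=params.n),
            ]
        )
    coords = pd.DataFrame(xy, index=inds, columns=["lat", "lon"])
    qdf = pd.DataFrame(
        q, index=inds, columns=[f"K{k + 1}" for k in range(params.K)]
    )
    return SimulatedPanel(table, qdf, freqs, coords, params, seed)
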
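"""Diversity, identity and distance statistics on SSR genotype tables.

Per-locus statistics follow the standard frequency-based definitions
used by PowerMarker/GenAlEx-style reporting.  With allele frequencies
p_i at one locus:

    Na   = number of observed alleles
    Ne   = 1 / sum p_i^2                      (effective alleles)
    He   = 1 - sum p_i^2                      (Nei gene diversity)
    Ho   = fraction of heterozygous non-missing individuals
    I    = -sum p_i ln p_i                    (Shannon index)
    PIC  = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4
    PI   = 2 (sum p_i^2)^2 - sum p_i^4        (prob. of identity)
    PIsibs = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4

All of these use the diploid view of the table (two allele draws per
non-missing individual).  The module also provides band-sharing genetic
similarity, a permutation Mantel test, haversine geographic distances,
principal coordinate analysis, and UPGMA / neighbor-joining trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "allele_freqs",
    "diversity",
    "identity_stats",
    "multilocus_match",
    "gs_matrix",
    "shared_allele_distance",
    "mantel",
    "MantelResult",
    "geo_distance",
    "pcoa",
    "PCoAResult",
    "build_tree",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# per-locus frequency statistics

def allele_freqs(table: GenotypeTable, locus: str) -> dict[int, float]:
    """Allele frequencies at one locus over the diploid view.

    Each non-missing individual contributes two allele copies; the
    returned frequencies sum to 1.  Raises on an all-missing locus.
    """
    counts: dict[int, int] = {}
    for ind in table.individuals:
        dip = table.diploid(ind, locus)
        if dip is None:
            continue
        for a in dip:
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        raise ValueError(f"locus {locus!r} has no non-missing genotypes")
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())}


def _freq_moments(p: np.ndarray) -> tuple[float, float]:
    return float(np.sum(p**2)), float(np.sum(p**4))


def diversity(table: GenotypeTable, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-locus Na, Ne, Ho, He, I and PIC, with an unweighted mean row.

    ``unbiased_he`` applies the 2n/(2n-1) small-sample correction to He
    (off by default, matching plain Nei gene diversity).
    """
    rows = {}
    for locus in table.loci:
        freqs = allele_freqs(table, locus)
        p = np.array(list(freqs.values()))
        sum2, sum4 = _freq_moments(p)
        dips = [
            table.diploid(ind, locus)
            for ind in table.individuals
            if not table.is_missing(ind, locus)
        ]
        n = len(dips)
        he = 1.0 - sum2
        if unbiased_he and n > 1:
            he *= 2 * n / (2 * n - 1)
        rows[locus] = {
            "Na": len(p),
            "Ne": 1.0 / sum2,
            "Ho": sum(a != b for a, b in dips) / n,
            "He": he,
            "I": float(-np.sum(p * np.log(p))),
            "PIC": 1.0 - sum2 - sum2**2 + sum4,
            "n": n,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[table.loci]
    df.loc["Mean"] = df.mean()
    return df


def identity_stats(
    table: GenotypeTable, order: str = "ascending_pi"
) -> pd.DataFrame:
    """Per-locus probability of identity for unrelated pairs (PI) and for
    full sibs (PIsibs), with running products over an ordered locus set.

    ``order``: ``ascending_pi`` accumulates most-informative loci first
    (smallest PI); ``table`` keeps the table's locus order.  Cumulative
    columns are non-increasing as loci are added.
    """
    recs = {}
    for locus in table.loci:
        p = np.array(list(allele_freqs(table, locus).values()))
        sum2, sum4 = _freq_moments(p)
        recs[locus] = {
            "PI": 2.0 * sum2**2 - sum4,
            "PIsibs": 0.25 + 0.5 * sum2 + 0.5 * sum2**2 - 0.25 * sum4,
        }
    df = pd.DataFrame.from_dict(recs, orient="index").loc[table.loci]
    if order == "ascending_pi":
        df = df.sort_values("PI", kind="stable")
    elif order != "table":
        raise ValueError(f"unknown order {order!r}")
    df["cum_PI"] = df["PI"].cumprod()
    df["cum_PIsibs"] = df["PIsibs"].cumprod()
    return df


def multilocus_match(table: GenotypeTable) -> list[tuple[str, str]]:
    """Pairs of individuals with identical diploid genotypes at every
    mutually non-missing locus (requiring at least one shared locus)."""
    genos = {
        ind: {
            loc: tuple(sorted(table.diploid(ind, loc)))
            for loc in table.loci
            if not table.is_missing(ind, loc)
        }
        for ind in table.individuals
    }
    out = []
    for a, b in itertools.combinations(table.individuals, 2):
        shared = genos[a].keys() & genos[b].keys()
        if shared and all(genos[a][l] == genos[b][l] for l in shared):
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# similarity / distance matrices

def _band_matrix(table: GenotypeTable) -> np.ndarray:
    """Binary presence matrix of individuals x (locus, size) bands built
    from all recorded sizes; missing cells score absent for every band."""
    bands = []
    for loc in table.loci:
        sizes = sorted(
            {s for ind in table.individuals for s in table.alleles(ind, loc)}
        )
        bands.extend((loc, s) for s in sizes)
    idx = {b: j for j, b in enumerate(bands)}
    mat = np.zeros((table.n_individuals(), len(bands)), dtype=bool)
    for i, ind in enumerate(table.individuals):
        for loc in table.loci:
            for s in table.alleles(ind, loc):
                mat[i, idx[(loc, s)]] = True
    return mat


def gs_matrix(
    table: GenotypeTable, coefficient: str = "simple_matching"
) -> pd.DataFrame:
    """Pairwise genetic similarity from band presence/absence.

    ``simple_matching``: (shared presences + shared absences) / bands;
    ``dice``: 2a / (2a + b + c).  Symmetric with unit diagonal; the
    corresponding genetic distance is ``1 - GS``.
    """
    x = _band_matrix(table).astype(float)
    n, nb = x.shape
    a = x @ x.T  # shared presences
    if coefficient == "simple_matching":
        d = (1 - x) @ (1 - x).T
        gs = (a + d) / nb
    elif coefficient == "dice":
        row = x.sum(axis=1)
        denom = row[:, None] + row[None, :]
        with np.errstate(invalid="ignore"):
            gs = np.where(denom > 0, 2 * a / denom, 1.0)
    else:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    np.fill_diagonal(gs, 1.0)
    ids = table.individuals
    return pd.DataFrame(gs, index=ids, columns=ids)


def shared_allele_distance(table: GenotypeTable) -> pd.DataFrame:
    """1 - (mean proportion of shared alleles) over the diploid view,
    averaged across mutually non-missing loci."""
    ids = table.individuals
    n = len(ids)
    d = np.zeros((n, n))
    dips = {
        (ind, loc): table.diploid(ind, loc)
        for ind in ids
        for loc in table.loci
    }
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            vals = []
            for loc in table.loci:
                ga, gb = dips[(a, loc)], dips[(b, loc)]
                if ga is None or gb is None:
                    continue
                ca, cb = list(ga), list(gb)
                shared = 0
                for al in ca:
                    if al in cb:
                        cb.remove(al)
                        shared += 1
                vals.append(shared / 2.0)
            d[i, j] = d[j, i] = 1.0 - float(np.mean(vals)) if vals else 1.0
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


def _as_square(m, name: str) -> tuple[np.ndarray, list | None]:
    if isinstance(m, pd.DataFrame):
        labels = list(m.index)
        arr = m.to_numpy(dtype=float)
    else:
        labels = None
        arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(arr, arr.T):
        raise ValueError(f"{name} is not symmetric")
    return arr, labels


def mantel(
    d_genetic,
    d_geo,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    p-value is one-sided upper, ``(1 + #{r_perm >= r_obs})/(n_perm+1)``,
    permuting individuals of the second matrix.  Matrices given as
    DataFrames must share the same ordering of ids.
    """
    a, la = _as_square(d_genetic, "d_genetic")
    b, lb = _as_square(d_geo, "d_geo")
    if a.shape != b.shape:
        raise ValueError("matrix sizes differ")
    if la is not None and lb is not None and la != lb:
        raise ValueError("matrix orderings differ")
    n = a.shape[0]
    tri = np.tril_indices(n, k=-1)
    va = a[tri]
    r_obs = float(np.corrcoef(va, b[tri])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb = b[np.ix_(perm, perm)][tri]
        if np.corrcoef(va, vb)[0, 1] >= r_obs:
            count += 1
    return MantelResult(r_obs, (1 + count) / (n_perm + 1), n_perm, seed)


def geo_distance(coords: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km from a table with
    ``lat``/``lon`` columns in decimal degrees (Earth radius 6371 km)."""
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    ids = list(coords.index)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# ordination and trees

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, sums to 100


def pcoa(dist) -> PCoAResult:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering of -D^2/2, eigendecomposition, axes ordered
    by eigenvalue.  Negative eigenvalues are dropped from both the axes
    and the variance denominator; each axis's sign is fixed by making
    its largest-magnitude coordinate positive.
    """
    d, labels = _as_square(dist, "dist")
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ b @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals[0])) if n else 0.0
    keep = vals > tol
    vals = vals[keep]
    coords = vecs[:, keep] * np.sqrt(vals)
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    pct = 100.0 * vals / vals.sum() if vals.size else vals
    if labels is None:
        labels = list(range(n))
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(pd.DataFrame(coords, index=labels, columns=cols),
                      vals, pct)


def _upgma_newick(d: np.ndarray, labels: list[str]) -> str:
    """UPGMA agglomeration with lexicographic tie-breaking on the
    smallest member label of each cluster."""
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    d = d[np.ix_(order, order)].astype(float)
    labels = [labels[i] for i in order]
    clusters = {i: [i] for i in range(len(labels))}
    newick = {i: labels[i] for i in range(len(labels))}
    height = {i: 0.0 for i in range(len(labels))}
    key = {i: labels[i] for i in range(len(labels))}
    dist = {
        frozenset((i, j)): d[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    nxt = len(labels)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1],) + tuple(sorted(key[c] for c in kv[0])),
        )
        (ci, cj), h = best[0], best[1] / 2.0
        ci, cj = sorted(best[0], key=lambda c: key[c])
        bi, bj = h - height[ci], h - height[cj]
        node = nxt
        nxt += 1
        newick[node] = f"({newick[ci]}:{bi:.10g},{newick[cj]}:{bj:.10g})"
        height[node] = h
        key[node] = min(key[ci], key[cj])
        merged = clusters[ci] + clusters[cj]
        others = [c for c in clusters if c not in (ci, cj)]
        for c in others:
            num = (
                dist[frozenset((ci, c))] * len(clusters[ci])
                + dist[frozenset((cj, c))] * len(clusters[cj])
            )
            dist[frozenset((node, c))] = num / len(merged)
        for k2 in list(dist):
            if ci in k2 or cj in k2:
                del dist[k2]
        del clusters[ci], clusters[cj]
        clusters[node] = merged
    return newick[nxt - 1] + ";"


def build_tree(dist, method: str = "upgma") -> str:
    """Distance tree in Newick format, via ``upgma`` (mean-linkage,
    ultrametric) or ``nj`` (neighbor joining, via scikit-bio).

    Ties are broken deterministically by lexicographic leaf label
    (UPGMA reorders internally; NJ input is presented in lexicographic
    order).  Requires n >= 3 taxa.
    """
    d, labels = _as_square(dist, "dist")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    labels = [str(l) for l in labels]
    if method == "upgma":
        return _upgma_newick(d, labels)
    if method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj as _nj

        order = sorted(range(n), key=lambda i: labels[i])
        dm = DistanceMatrix(d[np.ix_(order, order)],
                            [labels[i] for i in order])
        tree = _nj(dm)
        return str(tree).strip()
    raise ValueError(f"unknown tree method {method!r}")
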
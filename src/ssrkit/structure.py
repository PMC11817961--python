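"""Admixture-model inference by EM, and the Evanno ΔK model choice.

The model is the standard admixture likelihood: individual *i* carries
ancestry proportions q_i on the K-simplex, cluster *k* carries allele
frequencies f_kl. at locus *l*, and each observed allele copy *a* is an
independent draw from the mixture sum_k q_ik f_kl,a.  Maximization is
by expectation-maximization, which is deterministic given a seed and
monotone in the log-likelihood; multiple random restarts guard against
local optima.

The per-K maximized log-likelihoods (over replicate seeds) feed the
Evanno table:  L'(K) = L(K) - L(K-1) on replicate means,
|L''(K)| = |L'(K+1) - L'(K)|, ΔK = |L''(K)| / sd(L(K)); the argmax of
ΔK over interior K estimates the number of clusters.  The score here
is a maximized log-likelihood rather than an MCMC marginal-likelihood
estimate; Evanno's construction only requires a consistent per-K score
with replicate spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "StructureResult",
    "em_admixture",
    "lnp_replicates",
    "evanno",
    "EvannoTable",
]


@dataclass
class StructureResult:
    K: int
    Q: pd.DataFrame  # individuals x K admixture proportions
    F: dict[str, pd.DataFrame]  # locus -> (K x alleles) frequencies
    loglik: float
    n_iter: int
    seed: int | None
    converged: bool


def _encode(table: GenotypeTable):
    """Per-locus integer-coded allele copies: (alleles list, n x 2 array
    of allele indices, -1 for missing)."""
    coded = []
    for loc in table.loci:
        alleles = sorted(
            {
                a
                for ind in table.individuals
                for a in (table.diploid(ind, loc) or ())
            }
        )
        idx = {a: j for j, a in enumerate(alleles)}
        arr = np.full((table.n_individuals(), 2), -1, dtype=int)
        for i, ind in enumerate(table.individuals):
            dip = table.diploid(ind, loc)
            if dip is not None:
                arr[i] = [idx[dip[0]], idx[dip[1]]]
        coded.append((loc, alleles, arr))
    return coded


def em_admixture(
    table: GenotypeTable,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_init: int = 5,
) -> StructureResult:
    """Fit the K-cluster admixture model by EM.

    Runs ``n_init`` random restarts (seeds derived from *seed*) and
    returns the best.  The log-likelihood is non-decreasing across
    iterations; convergence is declared when the improvement drops
    below *tol*.  Missing allele copies contribute nothing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if table.n_individuals() < K:
        raise ValueError("need at least K individuals")
    for ind in table.individuals:
        if all(table.is_missing(ind, loc) for loc in table.loci):
            raise ValueError(f"individual {ind!r} has no genotypes")
    coded = _encode(table)
    n = table.n_individuals()
    ss = np.random.SeedSequence(seed)
    best: tuple | None = None
    for child in ss.spawn(max(1, n_init)):
        rng = np.random.default_rng(child)
        res = _em_once(coded, n, K, rng, tol, max_iter)
        if best is None or res[2] > best[2]:
            best = res
    q, f, ll, it, conv = best
    qdf = pd.DataFrame(
        q, index=table.individuals, columns=[f"K{k + 1}" for k in range(K)]
    )
    fd = {
        loc: pd.DataFrame(
            f[j], index=[f"K{k + 1}" for k in range(K)], columns=alleles
        )
        for j, (loc, alleles, _) in enumerate(coded)
    }
    return StructureResult(K, qdf, fd, ll, it, seed, conv)


def _em_once(coded, n, K, rng, tol, max_iter):
    q = rng.dirichlet(np.ones(K), size=n)
    f = [
        rng.dirichlet(np.ones(len(alleles)), size=K)
        for _, alleles, _ in coded
    ]
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q_num = np.zeros((n, K))
        f_num = [np.zeros_like(fl) for fl in f]
        ll = 0.0
        for j, (_, _, arr) in enumerate(coded):
            for c in (0, 1):
                a = arr[:, c]
                obs = a >= 0
                if not obs.any():
                    continue
                w = q[obs] * f[j][:, a[obs]].T  # (n_obs, K)
                tot = w.sum(axis=1)
                ll += float(np.log(tot).sum())
                r = w / tot[:, None]
                q_num[obs] += r
                np.add.at(f_num[j].T, a[obs], r)
        q = q_num / q_num.sum(axis=1, keepdims=True)
        for j in range(len(f)):
            colsum = f_num[j].sum(axis=1, keepdims=True)
            # clusters with no responsibility mass keep their profile
            safe = colsum > 0
            f[j] = np.where(safe, f_num[j] / np.where(safe, colsum, 1.0), f[j])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            prev = ll
            break
        prev = ll
    return q, f, prev, it, converged


def lnp_replicates(
    table: GenotypeTable,
    k_range=range(2, 11),
    n_rep: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Maximized log-likelihood per (K, replicate) as an LnP(K) table
    with columns ``K, replicate, lnp``.

    Each replicate is a single EM start with its own derived seed, so
    replicate spread reflects local-optimum variability (which the
    Evanno denominator consumes).
    """
    ks = list(k_range)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ks) * n_rep)
    rows = []
    for a, k in enumerate(ks):
        for rep in range(n_rep):
            child = children[a * n_rep + rep]
            run_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            res = em_admixture(table, k, seed=run_seed, n_init=1)
            rows.append({"K": k, "replicate": rep + 1, "lnp": res.loglik})
    return pd.DataFrame(rows)


@dataclass
class EvannoTable:
    table: pd.DataFrame  # indexed by K: mean, sd, d1, d2, delta_k
    optimal_k: int | None


def evanno(lnp_table: pd.DataFrame) -> EvannoTable:
    """Evanno ΔK from an LnP(K) replicate table (columns K, replicate,
    lnp; importable from external STRUCTURE runs).

    Requires >= 3 consecutive K values with >= 2 replicates each.  ΔK is
    defined only for interior K; ties resolve toward smaller K; if every
    ΔK is zero no optimum is flagged (``optimal_k`` is None).
    """
    g = lnp_table.groupby("K")["lnp"]
    mean = g.mean()
    sd = g.std(ddof=1)
    counts = g.count()
    ks = sorted(mean.index)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per K to compute sd")
    df = pd.DataFrame({"mean_lnp": mean, "sd_lnp": sd, "n_rep": counts})
    df["d1"] = df["mean_lnp"].diff()  # L'(K)
    df["d2"] = df["d1"].shift(-1) - df["d1"]
    df["d2"] = df["d2"].abs()  # |L''(K)|
    interior = df.index[1:-1]
    bad = df.loc[interior, "sd_lnp"] == 0
    if bad.any():
        raise ValueError(
            "zero replicate sd at K="
            f"{list(df.loc[interior][bad].index)}; add replicates or jitter"
        )
    df["delta_k"] = df["d2"] / df["sd_lnp"]
    df.loc[[ks[0], ks[-1]], "delta_k"] = np.nan
    dk = df["delta_k"].dropna()
    optimal = None
    if len(dk) and dk.max() > 0:
        optimal = int(dk[dk == dk.max()].index.min())
    return EvannoTable(df, optimal)
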
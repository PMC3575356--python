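"""Per-unit diversity and between-unit differentiation statistics.

Diversity: unbiased expected heterozygosity H_e = (2n/(2n-1))(1 - sum p_i^2),
observed heterozygosity H_o from per-individual genotypes, and a
multi-allelic exact Hardy–Weinberg test (complete enumeration up to three
alleles, Monte-Carlo otherwise) with a one-sided heterozygote-deficit
variant — the study's H_e excess makes the deficit direction the one of
interest.

Differentiation: Hudson's K_ST on sequence differences with a permutation
test, Weir–Cockerham theta (multi-allelic F_ST from genotypes), and the
heterozygosity-standardised pair Hedrick's G'_ST / Jost's D with
nearly-unbiased H_S / H_T estimators and harmonic-mean sample size.
Negative estimates are reported as computed, never truncated.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "heterozygosity",
    "observed_heterozygosity",
    "HweResult",
    "hwe_test",
    "kst",
    "fst_weir_cockerham",
    "DifferentiationEstimates",
    "gst_prime_and_jost_d",
    "regional_aggregate",
]


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def heterozygosity(
    counts: Mapping[str, int] | Sequence[int],
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Unbiased expected heterozygosity from allele counts, with bootstrap SE.

    H_e = (2n / (2n - 1)) (1 - sum p_i^2) where 2n is the total allele
    count.  The standard error resamples the 2n alleles with replacement
    (0 replicates -> SE reported as NaN).
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if vals.size == 0 or vals.sum() == 0:
        raise ValueError("no alleles counted")
    if (vals < 0).any():
        raise ValueError("negative allele count")

    def _he(v: np.ndarray) -> float:
        tot = v.sum()
        if tot < 2:
            return 0.0
        p = v / tot
        return float(tot / (tot - 1) * (1.0 - np.square(p).sum()))

    he = _he(vals)
    se = math.nan
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        tot = int(vals.sum())
        p = vals / tot
        reps = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            resampled = rng.multinomial(tot, p)
            reps[r] = _he(resampled.astype(float))
        se = float(np.std(reps, ddof=1))
    return he, se


def observed_heterozygosity(genotypes: Iterable[tuple[str, str]]) -> float:
    """Fraction of individuals whose two alleles differ."""
    pairs = list(genotypes)
    if not pairs:
        raise ValueError("no genotypes")
    return sum(a != b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    p_exact: float
    p_deficit: float
    method: str  # "enumeration" | "monte_carlo" | "undefined"
    n_individuals: int
    n_alleles: int

    @property
    def defined(self) -> bool:
        return self.method != "undefined"


def _log_table_prob(het: int, genotype_counts: np.ndarray, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    n = genotype_counts.sum()
    two_n = allele_counts.sum()
    return float(
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het * math.log(2.0)
        - gammaln(two_n + 1)
        - gammaln(genotype_counts + 1).sum()
    )


def _genotype_matrix(genotypes: Sequence[tuple[str, str]]):
    alleles = sorted({a for g in genotypes for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    table = np.zeros((k, k), dtype=int)
    for a, b in genotypes:
        i, j = sorted((index[a], index[b]))
        table[i, j] += 1
    return alleles, table


def _table_stats(table: np.ndarray):
    k = table.shape[0]
    allele = np.zeros(k, dtype=int)
    het = 0
    counts = []
    for i in range(k):
        for j in range(i, k):
            c = table[i, j]
            counts.append(c)
            allele[i] += c
            allele[j] += c
            if i != j:
                het += c
    return allele, het, np.array(counts)


def _enumerate_tables(allele_counts: np.ndarray):
    """Yield (het, genotype-count vector) over all tables with these margins (k <= 3)."""
    k = len(allele_counts)
    het_pairs = list(itertools.combinations(range(k), 2))

    def rec(pair_idx: int, hets: list[int]):
        if pair_idx == len(het_pairs):
            homs = allele_counts.copy().astype(int)
            for (i, j), h in zip(het_pairs, hets):
                homs[i] -= h
                homs[j] -= h
            if (homs < 0).any() or (homs % 2).any():
                return
            vec = []
            hh = dict(zip(het_pairs, hets))
            for i in range(k):
                for j in range(i, k):
                    vec.append(homs[i] // 2 if i == j else hh[(i, j)])
            yield sum(hets), np.array(vec)
            return
        i, j = het_pairs[pair_idx]
        for h in range(min(allele_counts[i], allele_counts[j]) + 1):
            yield from rec(pair_idx + 1, hets + [h])

    yield from rec(0, [])


def hwe_test(
    genotypes: Sequence[tuple[str, str]],
    mc_reps: int = 100_000,
    seed: int | None = None,
    max_enumeration_alleles: int = 3,
) -> HweResult:
    """Exact test of Hardy–Weinberg proportions from per-individual genotypes.

    The two-sided p-value sums the conditional probabilities of all
    genotype tables (given the observed allele counts) no more probable
    than the observed one; the one-sided variant sums tables with no more
    heterozygotes than observed.  Complete enumeration is used for up to
    ``max_enumeration_alleles`` alleles, otherwise a Monte-Carlo exact
    test that shuffles the allele vector into random pairings.
    """
    n = len(genotypes)
    alleles, table = _genotype_matrix(genotypes)
    k = len(alleles)
    if n < 2 or k < 2:
        return HweResult(math.nan, math.nan, "undefined", n, k)
    allele_counts, obs_het, obs_vec = _table_stats(table)
    obs_logp = _log_table_prob(obs_het, obs_vec, allele_counts)
    tol = 1e-9

    if k <= max_enumeration_alleles:
        p_exact = p_deficit = 0.0
        for het, vec in _enumerate_tables(allele_counts):
            lp = _log_table_prob(het, vec, allele_counts)
            prob = math.exp(lp)
            if lp <= obs_logp + tol:
                p_exact += prob
            if het <= obs_het:
                p_deficit += prob
        return HweResult(min(p_exact, 1.0), min(p_deficit, 1.0), "enumeration", n, k)

    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), allele_counts)
    hits_exact = hits_deficit = 0
    kk = k
    for _ in range(mc_reps):
        rng.shuffle(pool)
        pairs = pool.reshape(-1, 2)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        flat = lo * kk + hi
        counts = np.bincount(flat, minlength=kk * kk)
        vec = []
        het = 0
        for i in range(kk):
            for j in range(i, kk):
                c = counts[i * kk + j]
                vec.append(c)
                if i != j:
                    het += c
        lp = _log_table_prob(het, np.array(vec), allele_counts)
        if lp <= obs_logp + tol:
            hits_exact += 1
        if het <= obs_het:
            hits_deficit += 1
    p_exact = (hits_exact + 1) / (mc_reps + 1)
    p_deficit = (hits_deficit + 1) / (mc_reps + 1)
    return HweResult(p_exact, p_deficit, "monte_carlo", n, k)


# ---------------------------------------------------------------------------
# Hudson's K_ST
# ---------------------------------------------------------------------------


def _pairwise_diffs(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (arr[i + 1 :] != arr[i]).sum(axis=1)
    return d + d.T


def _kst_from_matrix(d: np.ndarray, sizes: Sequence[int]) -> float:
    bounds = np.cumsum([0, *sizes])
    n = bounds[-1]
    within = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        m = b - a
        within.append(0.0 if m < 2 else d[a:b, a:b].sum() / (m * (m - 1)))
    k_s = sum(w * m / n for w, m in zip(within, sizes))
    k_t = d.sum() / (n * (n - 1))
    if k_t == 0:
        return 0.0
    return 1.0 - k_s / k_t


def kst(
    pops: Sequence[Sequence[str]],
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Hudson's K_ST = 1 - K_S / K_T on sequence samples, with permutation p.

    K_S is the sample-size-weighted mean within-population pairwise
    difference, K_T the pooled mean pairwise difference.  Significance
    comes from permuting sequences among populations.  If every sequence
    is identical the statistic is 0 with p = 1.
    """
    if len(pops) < 2 or any(len(p) < 2 for p in pops):
        raise ValueError("need >= 2 populations with >= 2 sequences each")
    seqs = [s for pop in pops for s in pop]
    sizes = [len(p) for p in pops]
    d = _pairwise_diffs(seqs)
    obs = _kst_from_matrix(d, sizes)
    if d.sum() == 0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    idx = np.arange(len(seqs))
    hits = 0
    for _ in range(permutations):
        rng.shuffle(idx)
        perm = d[np.ix_(idx, idx)]
        if _kst_from_matrix(perm, sizes) >= obs:
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _theta_components(pops: Sequence[Sequence[tuple[str, str]]]):
    alleles = sorted({a for pop in pops for g in pop for a in g})
    r = len(pops)
    n_i = np.array([len(pop) for pop in pops], dtype=float)
    nbar = n_i.mean()
    n_c = (r * nbar - np.square(n_i).sum() / (r * nbar)) / (r - 1)
    num = den = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum((a == allele) + (b == allele) for a, b in pop) / (2 * len(pop)) for pop in pops]
        )
        h_i = np.array(
            [sum((a == allele) != (b == allele) for a, b in pop) / len(pop) for pop in pops]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * np.square(p_i - pbar)).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (
            nbar
            / n_c
            * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num, den


def fst_weir_cockerham(
    pops: Sequence[Sequence[tuple[str, str]]],
    permutations: int = 0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Multi-allelic Weir–Cockerham theta from per-individual genotypes.

    Per-allele variance components are summed over alleles
    (theta = sum a / sum (a + b + c)); slightly negative estimates are
    legitimate and returned as computed.  The permutation p shuffles
    individuals among populations (0 permutations -> p reported NaN).
    A pooled-monomorphic sample has no defined theta (NaN, p NaN).
    """
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    num, den = _theta_components(pops)
    if den == 0:
        return math.nan, math.nan
    obs = num / den
    if permutations <= 0:
        return obs, math.nan
    rng = np.random.default_rng(seed)
    genos = [g for pop in pops for g in pop]
    sizes = [len(p) for p in pops]
    bounds = np.cumsum([0, *sizes])
    hits = 0
    for _ in range(permutations):
        rng.shuffle(genos)
        shuffled = [genos[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        pn, pd = _theta_components(shuffled)
        if pd != 0 and pn / pd >= obs:
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# Hedrick's G'_ST and Jost's D
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationEstimates:
    g_st: float
    g_st_prime: float
    jost_d: float
    h_s: float
    h_t: float
    defined: bool = True


def gst_prime_and_jost_d(
    pops: Sequence[Mapping[str, int]],
) -> DifferentiationEstimates:
    """Hedrick's G'_ST and Jost's D from per-population allele counts.

    Uses the nearly-unbiased estimators with harmonic-mean sample size
    (n individuals = half the allele count): H_S,est = 2ñ/(2ñ-1) H_S and
    H_T,est = H_T + H_S,est/(2ñk).  Then G'_ST = G_ST (k-1+H_S)/[(k-1)(1-H_S)]
    and D_est = k/(k-1) (H_T,est - H_S,est)/(1 - H_S,est).  With H_S
    exactly 1 the standardisation is undefined and flagged.
    """
    k = len(pops)
    if k < 2:
        raise ValueError("need >= 2 populations")
    alleles = sorted({a for pop in pops for a in pop})
    freqs = []
    n_ind = []
    for pop in pops:
        tot = sum(pop.values())
        if tot == 0:
            raise ValueError("population with no alleles counted")
        freqs.append(np.array([pop.get(a, 0) / tot for a in alleles]))
        n_ind.append(tot / 2.0)
    freqs = np.array(freqs)
    h_s = float(np.mean(1.0 - np.square(freqs).sum(axis=1)))
    h_t = float(1.0 - np.square(freqs.mean(axis=0)).sum())
    n_harm = k / np.sum(1.0 / np.array(n_ind))
    hs_est = (2 * n_harm) / (2 * n_harm - 1) * h_s
    ht_est = h_t + hs_est / (2 * n_harm * k)
    if ht_est == 0:
        return DifferentiationEstimates(0.0, 0.0, 0.0, hs_est, ht_est)
    g_st = (ht_est - hs_est) / ht_est
    if hs_est >= 1.0:
        return DifferentiationEstimates(g_st, math.nan, math.nan, hs_est, ht_est, False)
    g_st_prime = g_st * (k - 1 + hs_est) / ((k - 1) * (1 - hs_est))
    jost_d = k / (k - 1) * (ht_est - hs_est) / (1 - hs_est)
    return DifferentiationEstimates(g_st, g_st_prime, jost_d, hs_est, ht_est)


# ---------------------------------------------------------------------------
# regional aggregation
# ---------------------------------------------------------------------------


def regional_aggregate(pairwise, region_map: Mapping[str, str], stats: Sequence[str]):
    """Arithmetic means of pairwise statistics over within-region unit pairs.

    ``pairwise`` is a DataFrame with columns ``unit1``, ``unit2`` and the
    statistics named in ``stats``; ``region_map`` assigns each unit to a
    region.  A region with fewer than two represented units yields NaN.
    """
    import pandas as pd

    regions = sorted(set(region_map.values()))
    rows = []
    for region in regions:
        members = {u for u, r in region_map.items() if r == region}
        sel = pairwise[
            pairwise["unit1"].isin(members) & pairwise["unit2"].isin(members)
        ]
        row = {"region": region, "n_pairs": len(sel)}
        for s in stats:
            row[s] = float(sel[s].mean()) if len(sel) else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
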
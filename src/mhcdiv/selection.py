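"""Counting-method selection statistics on codon alignments.

Implements the modified Nei–Gojobori method: potential synonymous /
nonsynonymous site counts weight transitional changes by the
transition/transversion bias R, observed differences between codons are
averaged over all minimal-length mutational pathways (pathways through
stop codons excluded), and proportions are corrected for multiple hits
with the Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).

On top of the pairwise machinery sit the partitioned dN/dS (PBR /
non-PBR / entire region, as ratio of mean distances with codon-bootstrap
standard errors), the mean pairwise count of nonsynonymous PBR
differences K_B, the synonymous nucleotide diversity pi_S, and the
TMRCA estimate from the maximum pairwise synonymous distance under a
molecular clock (d_max = 2 mu T for two diverging lineages).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .alignment import CodonAlignment
from .allotypes import PbrMask

__all__ = [
    "SelectionConfig",
    "PairwiseDnDs",
    "PartitionStats",
    "SelectionSummary",
    "jc_correct",
    "jc_invert",
    "pairwise_dn_ds",
    "partitioned_dnds",
    "kb_statistic",
    "pi_s",
    "tmrca",
]

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_STOPS = set(standard_dna_table.stop_codons)
AA = {c: ("*" if c in _STOPS else standard_dna_table.forward_table[c]) for c in CODONS}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SelectionConfig:
    """Tunables for the counting-method statistics.

    R is the transition/transversion bias used in site counting (the
    study's ML estimate for bear DQB exon 2 is 1.58); mu is the neutral
    synonymous substitution rate per site per year used for the clock.
    """

    R: float = 1.58
    bootstrap_reps: int = 1000
    mu: float = 3.5e-9
    seed: int | None = None
    exclude_saturated: bool = False

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap replicates must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


# ---------------------------------------------------------------------------
# Jukes-Cantor correction
# ---------------------------------------------------------------------------


def jc_correct(p: float) -> float:
    """JC multiple-hit correction; returns +inf when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_invert(d: float) -> float:
    """Inverse of :func:`jc_correct` for finite distances."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------------
# per-codon potential sites and pathway-averaged differences
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def codon_site_counts(R: float) -> tuple[np.ndarray, np.ndarray]:
    """Potential synonymous / nonsynonymous sites per codon, weighted by R.

    Each of the three positions contributes one site, split between the
    synonymous and nonsynonymous classes in proportion to the R-weighted
    fraction of single-base changes that are synonymous.  Changes that
    create a stop codon are excluded and the remaining weights
    renormalized; stop codons themselves get NaN.
    """
    S = np.full(64, np.nan)
    N = np.full(64, np.nan)
    for ci, codon in enumerate(CODONS):
        if AA[codon] == "*":
            continue
        s_total = 0.0
        for pos in range(3):
            wsum = syn = 0.0
            for b in BASES:
                if b == codon[pos]:
                    continue
                new = codon[:pos] + b + codon[pos + 1 :]
                if AA[new] == "*":
                    continue
                w = R if b == _TRANSITION[codon[pos]] else 1.0
                wsum += w
                if AA[new] == AA[codon]:
                    syn += w
            if wsum > 0:
                s_total += syn / wsum
        S[ci] = s_total
        N[ci] = 3.0 - s_total
    return S, N


@lru_cache(maxsize=1)
def codon_diff_counts() -> tuple[np.ndarray, np.ndarray]:
    """Pathway-averaged synonymous / nonsynonymous differences per codon pair.

    All minimal-length mutational pathways between the two codons are
    enumerated with equal weight; pathways passing through a stop codon
    are excluded (if every pathway is blocked, all are used).  Entries
    involving a stop endpoint are NaN.
    """
    SD = np.full((64, 64), np.nan)
    ND = np.full((64, 64), np.nan)
    for i, a in enumerate(CODONS):
        if AA[a] == "*":
            continue
        for j, b in enumerate(CODONS):
            if AA[b] == "*":
                continue
            if i == j:
                SD[i, j] = ND[i, j] = 0.0
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            paths = []
            for order in itertools.permutations(diff):
                cur = a
                syn = non = 0
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if AA[nxt] == "*":
                        blocked = True
                    if AA[nxt] == AA[cur]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                paths.append((blocked, syn, non))
            usable = [p for p in paths if not p[0]] or paths
            SD[i, j] = sum(p[1] for p in usable) / len(usable)
            ND[i, j] = sum(p[2] for p in usable) / len(usable)
    return SD, ND


def _encode(aln: CodonAlignment) -> np.ndarray:
    """(n_variants, n_codons) matrix of codon indices."""
    return np.array(
        [[CODON_INDEX[c] for c in aln.codons(v)] for v in aln.ids], dtype=int
    )


# ---------------------------------------------------------------------------
# pairwise dN / dS
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDnDs:
    d_n: float
    d_s: float
    p_n: float
    p_s: float
    n_nonsyn_sites: float
    n_syn_sites: float
    nonsyn_diffs: float
    syn_diffs: float
    saturated: bool = False


def pairwise_dn_ds(
    seq1: str,
    seq2: str,
    codon_indices: Sequence[int] | None = None,
    cfg: SelectionConfig | None = None,
) -> PairwiseDnDs:
    """Modified Nei–Gojobori distances between two gap-free coding sequences.

    ``codon_indices`` (1-based) restricts the computation to a partition;
    potential sites are averaged over the two sequences.  A saturated JC
    correction (p >= 3/4) is flagged and reported as +inf, never as a
    silent NaN.
    """
    cfg = cfg or SelectionConfig()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("sequence length not divisible by 3")
    n_codons = len(seq1) // 3
    idx = range(1, n_codons + 1) if codon_indices is None else codon_indices
    S, N = codon_site_counts(cfg.R)
    SD, ND = codon_diff_counts()
    ss = ns = sd = nd = 0.0
    for c in idx:
        a = CODON_INDEX[seq1[3 * (c - 1) : 3 * c]]
        b = CODON_INDEX[seq2[3 * (c - 1) : 3 * c]]
        if math.isnan(S[a]) or math.isnan(S[b]) or math.isnan(SD[a, b]):
            raise ValueError(f"stop codon at codon {c}; flag pseudogenes first")
        ss += (S[a] + S[b]) / 2
        ns += (N[a] + N[b]) / 2
        sd += SD[a, b]
        nd += ND[a, b]
    p_s = sd / ss if ss > 0 else math.nan
    p_n = nd / ns if ns > 0 else math.nan
    d_s = jc_correct(p_s) if not math.isnan(p_s) else math.nan
    d_n = jc_correct(p_n) if not math.isnan(p_n) else math.nan
    saturated = math.isinf(d_s) or math.isinf(d_n)
    if saturated:
        warnings.warn("Jukes-Cantor correction saturated (p >= 3/4)", stacklevel=2)
    return PairwiseDnDs(d_n, d_s, p_n, p_s, ns, ss, nd, sd, saturated)


# ---------------------------------------------------------------------------
# partitioned dN/dS with codon bootstrap
# ---------------------------------------------------------------------------


@dataclass
class PartitionStats:
    partition: str
    n_codons: int
    d_n: float
    d_s: float
    ratio: float  # ratio of mean d_N to mean d_S (NaN when d_S == 0)
    se_d_n: float
    se_d_s: float
    se_ratio: float
    n_syn_sites: float
    n_nonsyn_sites: float
    saturated_pairs: int = 0
    ratio_defined: bool = True


@dataclass
class SelectionSummary:
    partitions: dict[str, PartitionStats]
    n_variants: int
    kb: float | None = None
    kb_lineages: int | None = None
    d_tmrca: float | None = None
    se_d_tmrca: float | None = None
    tmrca_years: float | None = None
    mean_d_s: float | None = None
    tmrca_ratio: float | None = None
    extras: dict = field(default_factory=dict)


def _pair_arrays(codes: np.ndarray, R: float):
    """Per-pair, per-codon difference and site arrays for fast bootstrap."""
    S, N = codon_site_counts(R)
    SD, ND = codon_diff_counts()
    pairs = list(itertools.combinations(range(codes.shape[0]), 2))
    a = np.array([codes[i] for i, _ in pairs])
    b = np.array([codes[j] for _, j in pairs])
    if np.isnan(S[codes]).any():
        raise ValueError("alignment contains a stop codon; flag pseudogenes first")
    return {
        "sd": SD[a, b],
        "nd": ND[a, b],
        "ss": (S[a] + S[b]) / 2,
        "ns": (N[a] + N[b]) / 2,
    }


def _jc_vec(p: np.ndarray) -> np.ndarray:
    d = np.full_like(p, np.inf)
    ok = p < 0.75
    d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return d


def _partition_means(arr, cols: np.ndarray, exclude_saturated: bool):
    """Mean pairwise d_N and d_S over the given codon columns."""
    ss = arr["ss"][:, cols].sum(axis=1)
    ns = arr["ns"][:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_s = np.where(ss > 0, arr["sd"][:, cols].sum(axis=1) / ss, np.nan)
        p_n = np.where(ns > 0, arr["nd"][:, cols].sum(axis=1) / ns, np.nan)
    d_s = _jc_vec(p_s)
    d_n = _jc_vec(p_n)
    sat = np.isinf(d_s) | np.isinf(d_n)
    if exclude_saturated and sat.any():
        d_s, d_n = d_s[~sat], d_n[~sat]
    return float(np.mean(d_n)), float(np.mean(d_s)), int(sat.sum()), ss, ns


def partitioned_dnds(
    aln: CodonAlignment,
    mask: PbrMask,
    cfg: SelectionConfig | None = None,
) -> dict[str, PartitionStats]:
    """Mean pairwise d_N, d_S and their ratio for PBR / non-PBR / entire.

    Identical duplicate sequences are removed first; the ratio is the
    ratio of means (mean d_N over all unordered pairs divided by mean
    d_S), not the mean of per-pair ratios.  Standard errors come from
    resampling codons with replacement within each partition
    (stratified for the entire region), ``cfg.bootstrap_reps`` times.
    """
    cfg = cfg or SelectionConfig()
    aln = aln.deduplicate()
    if len(aln) < 2:
        raise ValueError("need >= 2 distinct coding variants")
    codes = _encode(aln)
    arr = _pair_arrays(codes, cfg.R)
    pbr = np.array(mask.codon_indices(aln.n_codons), dtype=int) - 1
    non = np.array(mask.non_pbr_codon_indices(aln.n_codons), dtype=int) - 1
    strata = {"pbr": [pbr], "non_pbr": [non], "entire": [pbr, non]}
    rng = np.random.default_rng(cfg.seed)

    out: dict[str, PartitionStats] = {}
    for name, parts in strata.items():
        cols = np.concatenate([p for p in parts if len(p)])
        d_n, d_s, sat, ss, ns = _partition_means(arr, cols, cfg.exclude_saturated)
        boot = np.empty((cfg.bootstrap_reps, 2))
        for r in range(cfg.bootstrap_reps):
            rcols = np.concatenate(
                [rng.choice(p, size=len(p), replace=True) for p in parts if len(p)]
            )
            bd_n, bd_s, _, _, _ = _partition_means(arr, rcols, cfg.exclude_saturated)
            boot[r] = (bd_n, bd_s)
        finite = np.isfinite(boot)
        se = [
            float(np.std(boot[finite[:, k], k], ddof=1)) if finite[:, k].sum() > 1 else math.nan
            for k in (0, 1)
        ]
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_ratio = boot[:, 0] / boot[:, 1]
        fr = np.isfinite(boot_ratio)
        se_ratio = float(np.std(boot_ratio[fr], ddof=1)) if fr.sum() > 1 else math.nan
        mean_ss = float(np.mean(ss))
        mean_ns = float(np.mean(ns))
        ratio_defined = mean_ss > 0 and d_s > 0 and math.isfinite(d_s)
        out[name] = PartitionStats(
            partition=name,
            n_codons=len(cols),
            d_n=d_n,
            d_s=d_s,
            ratio=d_n / d_s if ratio_defined else math.nan,
            se_d_n=se[0],
            se_d_s=se[1],
            se_ratio=se_ratio,
            n_syn_sites=mean_ss,
            n_nonsyn_sites=mean_ns,
            saturated_pairs=sat,
            ratio_defined=ratio_defined,
        )
    return out


# ---------------------------------------------------------------------------
# K_B, pi_S and TMRCA
# ---------------------------------------------------------------------------


def kb_statistic(aln: CodonAlignment, mask: PbrMask) -> tuple[float, int]:
    """Mean pairwise count of nonsynonymous differences at PBR codons.

    Pathway-averaged raw counts (no per-site scaling, no multiple-hit
    correction): K_B approximates the number of functionally distinct
    allelic lineages, returned rounded alongside the mean.
    """
    aln = aln.deduplicate()
    if len(aln) < 2:
        raise ValueError("need >= 2 coding variants")
    codes = _encode(aln)
    arr = _pair_arrays(codes, 1.0)
    cols = np.array(mask.codon_indices(aln.n_codons), dtype=int) - 1
    per_pair = arr["nd"][:, cols].sum(axis=1)
    kb = float(per_pair.mean())
    return kb, int(round(kb))


def pi_s(
    aln: CodonAlignment,
    frequencies: Mapping[str, float] | None = None,
    cfg: SelectionConfig | None = None,
    weighted: bool = True,
) -> float:
    """Synonymous nucleotide diversity: mean pairwise JC-corrected d_S.

    With ``weighted=True`` (default) pairs are weighted by allele
    frequencies, pi_S = sum_ij p_i p_j d_S(i, j); otherwise the plain
    mean over distinct-variant pairs is returned.  A monomorphic sample
    has pi_S = 0.
    """
    cfg = cfg or SelectionConfig()
    ids = aln.ids
    if weighted:
        if frequencies is None:
            raise ValueError("weighted pi_S needs allele frequencies")
        ids = [v for v in ids if frequencies.get(v, 0) > 0]
        missing = [v for v in frequencies if frequencies[v] > 0 and v not in aln]
        if missing:
            raise KeyError(f"frequencies reference unknown variant(s) {missing}")
        total = sum(frequencies[v] for v in ids)
        p = {v: frequencies[v] / total for v in ids}
    if len(ids) < 2:
        return 0.0
    total_pi = 0.0
    for i, j in itertools.combinations(ids, 2):
        d = pairwise_dn_ds(aln[i], aln[j], cfg=cfg).d_s
        if weighted:
            total_pi += 2 * p[i] * p[j] * d
        else:
            total_pi += d
    if not weighted:
        total_pi /= len(ids) * (len(ids) - 1) / 2
    return total_pi


def tmrca(
    aln: CodonAlignment, cfg: SelectionConfig | None = None
) -> tuple[float, float, float]:
    """TMRCA from the maximum pairwise synonymous distance.

    Returns ``(d_tmrca, years, ratio_to_mean)``: the divergence time is
    d_tmrca / (2 mu) — two lineages accumulate substitutions — and the
    ratio d_tmrca / mean d_S is reported against its neutral-panmictic
    expectation of 2 (larger values suggest old population structure).
    """
    cfg = cfg or SelectionConfig()
    aln = aln.deduplicate()
    if len(aln) < 2:
        raise ValueError("need >= 2 coding variants")
    ds = [
        pairwise_dn_ds(aln[i], aln[j], cfg=cfg).d_s
        for i, j in itertools.combinations(aln.ids, 2)
    ]
    d_max = max(ds)
    mean = float(np.mean(ds))
    years = d_max / (2.0 * cfg.mu)
    ratio = d_max / mean if mean > 0 else math.nan
    return d_max, years, ratio


def tmrca_from_distance(d_tmrca: float, mu: float = 3.5e-9) -> float:
    """Clock conversion alone: years = d_tmrca / (2 mu)."""
    return d_tmrca / (2.0 * mu)
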
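"""Binomial region test for intragenic recombination or gene conversion.

Exon 2 encodes the class II beta-1 domain: an N-terminal beta-sheet floor
followed by an alpha-helix wall.  Under clonal evolution the nucleotide
differences between two variants fall into the two regions in proportion
to region length; a significant excess of region-concentrated differences
(exact two-sided binomial test on s_A ~ Binomial(s, L_A / L)) signals a
reciprocal recombination or gene-conversion event between diverged
alleles.  The default boundary places the beta-sheet portion at
beta6–beta52 and the alpha-helix portion at beta53–beta94.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .alignment import BETA_OFFSET, CodonAlignment

__all__ = ["RegionSplit", "binomial_region_test"]


@dataclass(frozen=True)
class RegionSplit:
    """Contiguous two-region split of the analysis window by β position.

    ``boundary_beta`` is the first β position of the alpha-helix region;
    the beta-sheet region runs from the window start up to the boundary.
    """

    boundary_beta: int = 53
    offset: int = BETA_OFFSET

    def region_codons(self, n_codons: int) -> tuple[list[int], list[int]]:
        boundary_codon = self.boundary_beta - self.offset
        if not 1 < boundary_codon <= n_codons:
            raise ValueError(
                f"boundary β{self.boundary_beta} outside the analysis window"
            )
        sheet = list(range(1, boundary_codon))
        helix = list(range(boundary_codon, n_codons + 1))
        return sheet, helix

    def region_sites(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (length bp) for the two regions."""
        sheet, helix = self.region_codons(length // 3)
        mask = np.zeros(length, dtype=bool)
        for c in sheet:
            mask[3 * (c - 1) : 3 * c] = True
        return mask, ~mask


def _two_sided_binom(s_a: int, s: int, q: float) -> float:
    if s == 0:
        return 1.0
    return float(binomtest(s_a, s, q, alternative="two-sided").pvalue)


def binomial_region_test(
    aln: CodonAlignment,
    split: RegionSplit | None = None,
    scope: str = "per-pair",
) -> pd.DataFrame:
    """Exact binomial test of region-concentrated substitutions.

    ``scope="per-pair"`` tests every variant pair: with s nucleotide
    differences of which s_A fall in the beta-sheet region of length
    fraction q, the two-sided p-value of s_A ~ Binomial(s, q) is
    reported together with its Bonferroni correction over pairs.
    ``scope="pooled"`` applies one test to the segregating sites of the
    whole alignment.  Zero differences give p = 1 by convention.
    """
    split = split or RegionSplit()
    sheet_mask, _ = split.region_sites(aln.length)
    q = sheet_mask.sum() / aln.length
    mat = np.frombuffer(
        "".join(aln[v] for v in aln.ids).encode(), dtype="S1"
    ).reshape(len(aln), -1)

    if scope == "pooled":
        segregating = (mat != mat[0]).any(axis=0)
        s = int(segregating.sum())
        s_a = int((segregating & sheet_mask).sum())
        return pd.DataFrame(
            [
                {
                    "scope": "pooled",
                    "s": s,
                    "s_sheet": s_a,
                    "q_sheet": q,
                    "p_value": _two_sided_binom(s_a, s, q),
                }
            ]
        )
    if scope != "per-pair":
        raise ValueError("scope must be 'per-pair' or 'pooled'")

    rows = []
    ids = aln.ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        diff = mat[i] != mat[j]
        s = int(diff.sum())
        s_a = int((diff & sheet_mask).sum())
        rows.append(
            {
                "variant1": ids[i],
                "variant2": ids[j],
                "s": s,
                "s_sheet": s_a,
                "q_sheet": q,
                "p_value": _two_sided_binom(s_a, s, q),
            }
        )
    df = pd.DataFrame(rows)
    m = len(df)
    df["p_bonferroni"] = (df["p_value"] * m).clip(upper=1.0)
    df["significant"] = df["p_bonferroni"] < 0.05
    return df
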
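"""Allotype translation, PBR partition, Wu–Kabat variability and NJ clustering.

A nucleotide variant translates to a peptide; variants sharing a peptide
form one *allotype*.  Codon positions are partitioned into peptide-binding
residues (PBR) and non-PBR using a configurable mask of human-DRβ position
labels (the default ships the β-chain antigen-contact positions of the
human DR structure restricted to β6–β94).  Allotypes sharing the peptide
restricted to PBR positions form one *PBR type* — a proxy for functionally
distinct binding repertoires.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import BETA_OFFSET, CodonAlignment, VariantName

__all__ = [
    "PbrMask",
    "AllotypePanel",
    "translate_and_flag",
    "site_variability",
    "classify_pbr_types",
    "heterozygote_pbr_mismatch",
    "nj_pbr_tree",
    "neighbor_joining",
]


@dataclass(frozen=True)
class PbrMask:
    """Set of β-position labels designated peptide-binding residues.

    ``offset`` converts between 1-based codon indices and β labels
    (β = codon + offset); the default window starts at β6.
    """

    beta_positions: frozenset[int]
    offset: int = BETA_OFFSET

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_positions", frozenset(self.beta_positions))

    @classmethod
    def default(cls) -> "PbrMask":
        with resources.files("mhcdiv.data").joinpath("pbr_mask.yaml").open() as fh:
            return cls.from_yaml(fh)

    @classmethod
    def from_yaml(cls, source) -> "PbrMask":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        return cls(
            beta_positions=frozenset(int(p) for p in doc["beta_positions"]),
            offset=int(doc.get("offset", BETA_OFFSET)),
        )

    def codon_indices(self, n_codons: int) -> list[int]:
        """1-based codon indices inside the mask, restricted to the window."""
        return [
            c for c in range(1, n_codons + 1) if c + self.offset in self.beta_positions
        ]

    def non_pbr_codon_indices(self, n_codons: int) -> list[int]:
        pbr = set(self.codon_indices(n_codons))
        return [c for c in range(1, n_codons + 1) if c not in pbr]

    def contains_beta(self, beta: int) -> bool:
        return beta in self.beta_positions

    def __len__(self) -> int:
        return len(self.beta_positions)


@dataclass
class AllotypePanel:
    """Translated variants: allotype groups, peptides and pseudogene flags."""

    peptides: dict[str, str]  # variant id -> peptide
    pseudogenes: frozenset[str]  # variant ids with an internal stop
    allotypes: dict[str, list[str]]  # allotype id -> coding variant ids
    variant_allotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variant_allotype:
            self.variant_allotype = {
                v: a for a, members in self.allotypes.items() for v in members
            }

    @property
    def coding_variants(self) -> list[str]:
        return [v for v in self.peptides if v not in self.pseudogenes]

    @property
    def n_allotypes(self) -> int:
        return len(self.allotypes)

    def allotype_peptides(self) -> dict[str, str]:
        """One peptide per allotype (from its first member variant)."""
        return {a: self.peptides[members[0]] for a, members in self.allotypes.items()}


def translate_and_flag(aln: CodonAlignment) -> AllotypePanel:
    """Translate every variant; flag internal stop codons as pseudogenes.

    Stop codons are data, not errors: a flagged pseudogene is excluded
    from allotype grouping and selection statistics but stays available
    for genotype bookkeeping.
    """
    peptides = {vid: aln.translate(vid) for vid in aln.ids}
    pseudo = frozenset(v for v, pep in peptides.items() if "*" in pep)

    groups: dict[str, list[str]] = {}
    for vid in aln.ids:
        if vid in pseudo:
            continue
        groups.setdefault(peptides[vid], []).append(vid)

    allotypes: dict[str, str] = {}
    named: dict[str, list[str]] = {}
    for i, (pep, members) in enumerate(groups.items(), start=1):
        parsed = [VariantName.try_parse(v) for v in members]
        if all(p is not None for p in parsed) and len({p.allotype for p in parsed}) == 1:  # type: ignore[union-attr]
            key = f"{parsed[0].locus}*{parsed[0].allotype}"  # type: ignore[union-attr]
        else:
            key = f"allotype{i:02d}"
        if key in named:  # name collision across distinct peptides
            key = f"allotype{i:02d}"
        named[key] = members
    return AllotypePanel(peptides=peptides, pseudogenes=pseudo, allotypes=named)


def site_variability(panel: AllotypePanel, mask: PbrMask) -> pd.DataFrame:
    """Per-position residue counts and Wu–Kabat variability over allotypes.

    The Wu–Kabat index at a position is ``V = k N / n_max`` where ``k`` is
    the number of distinct residues, ``N`` the number of allotypes and
    ``n_max`` the count of the most common residue; ``V = 1`` iff the
    position is invariant.
    """
    peps = list(panel.allotype_peptides().values())
    if len(peps) < 2:
        raise ValueError("need at least 2 allotypes")
    n = len(peps)
    n_codons = len(peps[0])
    pbr = set(mask.codon_indices(n_codons))
    rows = []
    for c in range(1, n_codons + 1):
        column = [p[c - 1] for p in peps]
        counts = pd.Series(column).value_counts()
        k = len(counts)
        n_max = int(counts.iloc[0])
        rows.append(
            {
                "codon": c,
                "beta_position": c + mask.offset,
                "k_residues": k,
                "n_max": n_max,
                "wu_kabat": k * n / n_max,
                "polymorphic": k > 1,
                "in_pbr": c in pbr,
            }
        )
    return pd.DataFrame(rows).set_index("beta_position")


def polymorphic_site_summary(variability: pd.DataFrame) -> dict[str, int]:
    poly = variability[variability["polymorphic"]]
    return {
        "polymorphic_sites": int(len(poly)),
        "polymorphic_pbr": int(poly["in_pbr"].sum()),
        "polymorphic_non_pbr": int((~poly["in_pbr"]).sum()),
        "monomorphic_pbr": int(
            (variability["in_pbr"] & ~variability["polymorphic"]).sum()
        ),
    }


def classify_pbr_types(panel: AllotypePanel, mask: PbrMask) -> dict[str, list[str]]:
    """Partition allotypes by identical PBR-restricted peptide.

    Type ids ``PBR01, PBR02, ...`` are assigned by first occurrence in
    the panel, so the partition (though not the labels' spelling) is
    invariant under allotype relabeling.
    """
    allo_peps = panel.allotype_peptides()
    if not allo_peps:
        return {}
    n_codons = len(next(iter(allo_peps.values())))
    idx = [c - 1 for c in mask.codon_indices(n_codons)]
    groups: dict[str, list[str]] = {}
    for allo, pep in allo_peps.items():
        key = "".join(pep[i] for i in idx)
        groups.setdefault(key, []).append(allo)
    return {f"PBR{i:02d}": members for i, members in enumerate(groups.values(), 1)}


def heterozygote_pbr_mismatch(
    genotypes: Iterable[tuple[str, str]],
    panel: AllotypePanel,
    pbr_types: Mapping[str, list[str]],
) -> tuple[int, int]:
    """Count heterozygotes whose two alleles fall in different PBR types.

    ``genotypes`` yields (allele1, allele2) pairs of *variant* ids.
    Returns ``(mismatched, total_heterozygotes)``; homozygotes and
    pseudogene carriers are not heterozygotes for this purpose unless
    both alleles are coding.
    """
    allo_type = {
        allo: tid for tid, members in pbr_types.items() for allo in members
    }
    het = mismatch = 0
    for a1, a2 in genotypes:
        if a1 == a2:
            continue
        for a in (a1, a2):
            if a not in panel.peptides:
                raise KeyError(f"genotype references unknown variant {a!r}")
        if a1 in panel.pseudogenes or a2 in panel.pseudogenes:
            continue
        t1 = allo_type[panel.variant_allotype[a1]]
        t2 = allo_type[panel.variant_allotype[a2]]
        het += 1
        if t1 != t2:
            mismatch += 1
    return mismatch, het


# ---------------------------------------------------------------------------
# neighbor joining on count-of-differences distances
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(labels: Sequence[str], dist: np.ndarray) -> str:
    """Classic neighbor joining; returns an unrooted newick string.

    Deterministic: ties in the Q criterion are broken by joining the
    lexicographically smallest label pair; negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(l) for l in labels]
    names = list(labels)
    d = np.asarray(dist, dtype=float).copy()

    def join_key(i: int, j: int) -> tuple[str, str]:
        return tuple(sorted((names[i], names[j])))  # type: ignore[return-value]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, join_key(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best  # type: ignore[misc]
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        newd = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2 for k in range(n)])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], newd[keep]])
        d = np.hstack([d, np.append(newd[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(join_key(i, j))]

    # resolve the final 3-star with the closed form
    (a, b, c) = range(3)
    la = max((d[a, b] + d[a, c] - d[b, c]) / 2, 0.0)
    lb = max((d[a, b] + d[b, c] - d[a, c]) / 2, 0.0)
    lc = max((d[a, c] + d[b, c] - d[a, b]) / 2, 0.0)
    root = _Node(
        None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    return root.newick() + ";"


def nj_pbr_tree(peptides: Mapping[str, str]) -> str:
    """NJ tree (newick) on pairwise count-of-differences between peptides.

    Identical peptides are collapsed to their first-occurring id before
    tree building; at least 3 distinct peptides are required.
    """
    reps: dict[str, str] = {}
    for pid, pep in peptides.items():
        reps.setdefault(pep, pid)
    labels = list(reps.values())
    peps = list(reps.keys())
    if len(labels) < 3:
        raise ValueError("need at least 3 distinct peptides for a tree")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(x != y for x, y in zip(peps[i], peps[j]))
    return neighbor_joining(labels, d)
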
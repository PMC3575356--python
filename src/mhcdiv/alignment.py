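"""Core sequence and genotype-table containers.

The unit of analysis is a gap-free, equal-length, in-frame nucleotide
alignment of MHC class II exon-2 variants (a :class:`CodonAlignment`),
together with per-management-unit allele counts
(a :class:`UnitGenotypeTable`) and optional per-individual genotypes.

Coordinates are 1-based inclusive throughout: windows on the input
alignment, codon indices, and nucleotide positions.  The exon-2 amplicon
of the bear *DQB* locus is 270 bp; analyses use the first 267 bp
(89 complete codons), and codon 1 corresponds to residue β6 of the
human DRβ chain, so ``beta_position = codon_index + BETA_OFFSET``.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BETA_OFFSET",
    "CodonAlignment",
    "VariantName",
    "UnitGenotypeTable",
    "read_alignment",
    "write_alignment",
    "read_unit_table",
    "read_individual_genotypes",
    "collapse_to_allotypes",
]

#: codon 1 of the analysis window is residue β6 in human DRβ numbering
BETA_OFFSET = 5

_VALID = set("ACGT")


class AlignmentError(ValueError):
    """Raised when an input violates the alignment invariants."""


@dataclass(frozen=True)
class VariantName:
    """Parsed variant name of the form ``Locus*AASS``.

    The two digits after the asterisk identify the allotype (amino-acid
    sequence); the trailing two digits distinguish synonymous variants
    of the same allotype.
    """

    locus: str
    allotype: str
    suffix: str

    _RX = re.compile(r"^(?P<locus>[^*]+)\*(?P<allotype>\d{2})(?P<suffix>\d{2})$")

    @classmethod
    def parse(cls, name: str) -> "VariantName":
        m = cls._RX.match(name.strip())
        if m is None:
            raise ValueError(f"variant name {name!r} does not match Locus*AASS")
        return cls(m["locus"], m["allotype"], m["suffix"])

    @classmethod
    def try_parse(cls, name: str) -> "VariantName | None":
        try:
            return cls.parse(name)
        except ValueError:
            return None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.locus}*{self.allotype}{self.suffix}"


class CodonAlignment:
    """Gap-free equal-length nucleotide alignment read in frame.

    Parameters
    ----------
    sequences
        Mapping of variant id to an uppercase ACGT string.  All
        sequences must share one length divisible by three.
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        length: int | None = None
        for vid, seq in sequences.items():
            if vid in seqs:
                raise AlignmentError(f"duplicate variant id {vid!r}")
            s = str(seq).upper()
            bad = set(s) - _VALID
            if bad:
                raise AlignmentError(
                    f"record {vid!r} contains non-ACGT symbol(s) {sorted(bad)!r}"
                )
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise AlignmentError(
                    f"record {vid!r} has length {len(s)}, expected {length}"
                )
            seqs[vid] = s
        if not seqs:
            raise AlignmentError("alignment is empty")
        assert length is not None
        if length % 3:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        self._seqs = seqs
        self.length = length
        self.n_codons = length // 3

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self):
        return iter(self._seqs)

    def __getitem__(self, vid: str) -> str:
        return self._seqs[vid]

    def __contains__(self, vid: str) -> bool:
        return vid in self._seqs

    def items(self):
        return self._seqs.items()

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    # -- codon access --------------------------------------------------------
    def codon(self, vid: str, index: int) -> str:
        """Codon ``index`` (1-based) of variant ``vid``."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} outside 1..{self.n_codons}")
        s = self._seqs[vid]
        return s[3 * (index - 1) : 3 * index]

    def codons(self, vid: str) -> list[str]:
        s = self._seqs[vid]
        return [s[i : i + 3] for i in range(0, self.length, 3)]

    def beta_position(self, codon_index: int) -> int:
        """Human-DRβ residue label of a 1-based codon index."""
        return codon_index + BETA_OFFSET

    def translate(self, vid: str) -> str:
        return str(Seq(self._seqs[vid]).translate())

    # -- derived alignments --------------------------------------------------
    def subset(self, ids: Iterable[str]) -> "CodonAlignment":
        return CodonAlignment({v: self._seqs[v] for v in ids})

    def deduplicate(self) -> "CodonAlignment":
        """Keep the first variant of each identical nucleotide sequence."""
        seen: dict[str, str] = {}
        for vid, seq in self._seqs.items():
            seen.setdefault(seq, vid)
        return self.subset(sorted(seen.values(), key=self.ids.index))


def read_alignment(path: str | Path, window: tuple[int, int] | None = None) -> CodonAlignment:
    """Read a FASTA alignment, optionally trimming to a 1-based window.

    ``window=(1, 267)`` keeps the first 267 bp — the 89 complete codons
    of the 270-bp exon-2 amplicon.  All records must share one length
    before windowing and the windowed length must be divisible by 3.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    seqs: dict[str, str] = {}
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
        seqs[rec.id] = str(rec.seq).upper()
    if window is not None:
        start, end = window
        if not (1 <= start <= end <= length):
            raise AlignmentError(f"window {window} outside 1..{length}")
        seqs = {v: s[start - 1 : end] for v, s in seqs.items()}
    return CodonAlignment(seqs)


def write_alignment(aln: CodonAlignment, path: str | Path, width: int = 60) -> None:
    """Write the alignment as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(seq), id=vid, description="") for vid, seq in aln.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# genotype-count tables
# ---------------------------------------------------------------------------

#: the 12 sampled conservation and management units, west to east order as printed
UNIT_CODES = ["CS", "GAI", "SO", "EM", "SA", "NCA", "HO", "NK", "EC", "WC", "KH", "SK"]


@dataclass
class UnitGenotypeTable:
    """Per-management-unit allele counts, plus optional per-individual genotypes.

    ``counts`` is a variants × units DataFrame of non-negative integers
    (absent variant = 0).  ``n_individuals`` maps unit code to the number
    of sampled bears; when per-individual genotypes are available the
    column sums must equal ``2 n``.
    """

    counts: pd.DataFrame
    n_individuals: dict[str, int] | None = None
    genotypes: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative allele count")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate variant row {dup!r}")
        self.counts = self.counts.astype(int)
        if self.genotypes is not None and self.n_individuals is None:
            self.n_individuals = (
                self.genotypes.groupby("unit")["individual_id"].nunique().to_dict()
            )
        self.validate()

    def validate(self) -> None:
        if self.n_individuals is not None and self.genotypes is not None:
            for unit, n in self.n_individuals.items():
                if unit not in self.counts.columns:
                    continue
                total = int(self.counts[unit].sum())
                if total != 2 * n:
                    raise ValueError(
                        f"unit {unit}: allele counts sum to {total}, expected 2n = {2 * n}"
                    )

    @property
    def units(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def variants(self) -> list[str]:
        return list(self.counts.index)

    def unit_allele_counts(self, unit: str) -> dict[str, int]:
        """Nonzero allele counts for one unit."""
        col = self.counts[unit]
        return {v: int(c) for v, c in col.items() if c > 0}

    def unit_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def variant_totals(self) -> pd.Series:
        """Grand total of allele counts per variant across all units."""
        return self.counts.sum(axis=1)

    def allele_frequencies(self, unit: str | None = None) -> pd.Series:
        col = self.counts[unit] if unit else self.counts.sum(axis=1)
        total = col.sum()
        if total == 0:
            raise ValueError("no alleles counted")
        return col / total

    def unknown_variants(self, aln: CodonAlignment) -> list[str]:
        """Counted variant ids absent from the accompanying alignment."""
        return [v for v in self.variants if v not in aln]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        if self.n_individuals is not None:
            header = pd.DataFrame(
                [{u: self.n_individuals.get(u, 0) for u in out.columns}],
                index=["n_samples"],
            )
            out = pd.concat([header, out])
        out.to_csv(path, sep="\t", index_label="variant")


_N_ROW_NAMES = {"n_samples", "no. of sample", "no. of samples"}


def read_unit_table(path: str | Path) -> UnitGenotypeTable:
    """Read a delimited allele-count table (variants × unit codes).

    The first column holds variant names; a row named ``n_samples``
    (or "No. of sample") gives per-unit sample sizes.  Blank cells
    mean the variant was not observed (count 0).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df = df.fillna(0)
    n_individuals = None
    mask = df.index.str.lower().isin(_N_ROW_NAMES)
    if mask.any():
        n_individuals = {u: int(v) for u, v in df.loc[mask].iloc[0].items()}
        df = df.loc[~mask]
    try:
        df = df.astype(float).astype(int)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    return UnitGenotypeTable(counts=df, n_individuals=n_individuals)


def read_individual_genotypes(path: str | Path) -> pd.DataFrame:
    """Read per-individual genotypes (individual_id, unit, variant1, variant2)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"individual_id", "unit", "variant1", "variant2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype file missing column(s) {sorted(missing)}")
    return df


def genotype_table_from_individuals(genotypes: pd.DataFrame) -> UnitGenotypeTable:
    """Aggregate per-individual genotype pairs into an allele-count table."""
    rows: dict[str, dict[str, int]] = {}
    for _, rec in genotypes.iterrows():
        for allele in (rec["variant1"], rec["variant2"]):
            rows.setdefault(allele, {}).setdefault(rec["unit"], 0)
            rows[allele][rec["unit"]] += 1
    counts = pd.DataFrame(rows).T.fillna(0).astype(int)
    counts = counts.sort_index()
    return UnitGenotypeTable(counts=counts, genotypes=genotypes.copy())


def collapse_to_allotypes(
    aln: CodonAlignment, translations: Mapping[str, str]
) -> dict[str, list[str]]:
    """Group variants whose translations are identical peptides.

    Returns a partition mapping allotype key → list of variant ids (input
    order).  The key follows the naming convention — the shared two-digit
    allotype field when every member's name parses, otherwise the peptide
    itself.
    """
    missing = [v for v in aln.ids if v not in translations]
    if missing:
        raise ValueError(f"no translation for variant(s) {missing}")
    groups: dict[str, list[str]] = {}
    for vid in aln.ids:
        groups.setdefault(translations[vid], []).append(vid)

    out: dict[str, list[str]] = {}
    for peptide, members in groups.items():
        names = [VariantName.try_parse(v) for v in members]
        if all(n is not None for n in names):
            allos = {n.allotype for n in names}  # type: ignore[union-attr]
            key = f"{names[0].locus}*{allos.pop()}" if len(allos) == 1 else peptide  # type: ignore[union-attr]
        else:
            key = peptide
        if key in out:  # inconsistent naming: fall back to the peptide itself
            key = peptide
        out[key] = members
    return out
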
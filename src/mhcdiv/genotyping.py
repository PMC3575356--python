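"""Clone-based genotyping quality control.

Each individual is typed by cloning its PCR product and sequencing 8–22
clones; PCR point errors create near-duplicate artifact sequences, and
amplification bias can hide one allele of a heterozygote.  Two criteria
are implemented:

* **study** — a distinct clone sequence is a candidate allele when it has
  at least ``min_support`` clones or is already a validated variant seen
  in another individual; unsupported singletons are set aside as likely
  PCR errors.
* **conservative** — additionally discards any minor-variant sequence
  seen in this one individual alone that lies within fewer than
  ``artifact_distance_bp`` substitutions (Hamming distance <= 2 by
  default) of another sequence in the same clone set, the classic
  PCR-artifact rule.

An individual is excluded (never guessed) when more than two candidates
retain substantial support, when candidate ranks are tied at the
genotype boundary, or when an extreme minor-variant clone frequency is
not corroborated by direct-sequencing double peaks at the diagnostic
sites.  Every decision is recorded so exclusions stay auditable.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import CodonAlignment

__all__ = [
    "CloneSet",
    "QcConfig",
    "GenotypeCall",
    "call_genotype",
    "call_panel",
    "compare_criteria",
    "read_clone_sets",
]


@dataclass
class CloneSet:
    """Clone sequences of one individual with per-distinct-sequence counts."""

    individual_id: str
    counts: dict[str, int]  # distinct sequence -> number of clones
    unit: str | None = None
    double_peaks: frozenset[int] | None = None  # 1-based bp positions

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"{self.individual_id}: empty clone set")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError(f"{self.individual_id}: clone count < 1")
        lengths = {len(s) for s in self.counts}
        if len(lengths) != 1:
            raise ValueError(f"{self.individual_id}: clone length mismatch")

    @property
    def total_clones(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_clones(
        cls,
        individual_id: str,
        clones: Iterable[str],
        unit: str | None = None,
        double_peaks: Iterable[int] | None = None,
    ) -> "CloneSet":
        counts = dict(Counter(str(c).upper() for c in clones))
        peaks = frozenset(double_peaks) if double_peaks is not None else None
        return cls(individual_id, counts, unit, peaks)


@dataclass
class QcConfig:
    min_clones: int = 8
    max_variants_per_individual: int = 2
    artifact_distance_bp: int = 3  # "differs by less than 3 bp" -> Hamming <= 2
    mode: str = "study"  # "study" | "conservative"
    require_direct_seq_concordance: bool = False
    min_support: int = 2  # clones needed for a candidate not seen elsewhere
    extreme_minor_clones: int = 1  # minor support this low triggers the peak check

    def __post_init__(self) -> None:
        if self.min_clones < 1:
            raise ValueError("min_clones must be >= 1")
        if self.artifact_distance_bp < 1:
            raise ValueError("artifact_distance_bp must be >= 1")
        if self.mode not in ("study", "conservative"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class GenotypeCall:
    individual_id: str
    variants: tuple[str, ...]  # () when excluded; 1 seq = homozygote
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    artifacts: list[str] = field(default_factory=list)  # discarded sequences
    unit: str | None = None

    @property
    def genotype(self) -> tuple[str, str] | None:
        if self.excluded or not self.variants:
            return None
        if len(self.variants) == 1:
            return (self.variants[0], self.variants[0])
        return (self.variants[0], self.variants[1])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def call_genotype(
    clones: CloneSet,
    known: frozenset[str] | set[str] = frozenset(),
    cfg: QcConfig | None = None,
    panel_length: int | None = None,
) -> GenotypeCall:
    """Call one individual's genotype from its clone set.

    ``known`` holds sequences validated outside this individual (seen in
    other individuals or supplied as a reference panel).  See the module
    docstring for the study vs conservative rules.
    """
    cfg = cfg or QcConfig()
    if panel_length is not None and len(next(iter(clones.counts))) != panel_length:
        raise ValueError(
            f"{clones.individual_id}: clone length differs from panel length"
        )
    reasons: list[str] = []
    artifacts: list[str] = []
    # rank: most clones first, sequence as deterministic tiebreak
    ranked = sorted(clones.counts, key=lambda s: (-clones.counts[s], s))

    if clones.total_clones < cfg.min_clones:
        reasons.append(
            f"only {clones.total_clones} clones (< {cfg.min_clones}); call retained but flagged"
        )

    # --- artifact filtering -------------------------------------------------
    candidates: list[str] = []
    for seq in ranked:
        count = clones.counts[seq]
        if seq in known:
            candidates.append(seq)
            continue
        if count < cfg.min_support:
            artifacts.append(seq)
            reasons.append(f"{seq[:12]}…: {count} clone(s), unseen elsewhere: low support")
            continue
        candidates.append(seq)

    if cfg.mode == "conservative":
        survivors: list[str] = []
        for pos, seq in enumerate(candidates):
            is_minor = pos > 0
            if (
                is_minor
                and seq not in known
                and any(
                    _hamming(seq, other) < cfg.artifact_distance_bp
                    for other in clones.counts
                    if clones.counts[other] > clones.counts[seq]
                )
            ):
                artifacts.append(seq)
                reasons.append(
                    f"{seq[:12]}…: minor variant unseen elsewhere within "
                    f"<{cfg.artifact_distance_bp} bp of a same-set sequence: PCR artifact"
                )
                continue
            survivors.append(seq)
        candidates = survivors

    if not candidates:
        return GenotypeCall(
            clones.individual_id, (), True, reasons + ["no supported variant"], artifacts, clones.unit
        )

    # --- ambiguity ----------------------------------------------------------
    strong = [s for s in candidates if clones.counts[s] >= cfg.min_support]
    if len(strong) > cfg.max_variants_per_individual:
        reasons.append(
            f"{len(strong)} supported variants exceed the maximum of "
            f"{cfg.max_variants_per_individual}"
        )
        return GenotypeCall(clones.individual_id, (), True, reasons, artifacts, clones.unit)
    if len(candidates) > cfg.max_variants_per_individual:
        cut = clones.counts[candidates[cfg.max_variants_per_individual - 1]]
        nxt = clones.counts[candidates[cfg.max_variants_per_individual]]
        if cut == nxt:
            reasons.append("tied clone counts at the genotype boundary")
            return GenotypeCall(
                clones.individual_id, (), True, reasons, artifacts, clones.unit
            )
        dropped = candidates[cfg.max_variants_per_individual :]
        artifacts.extend(dropped)
        reasons.extend(f"{s[:12]}…: beyond top-{cfg.max_variants_per_individual}" for s in dropped)
        candidates = candidates[: cfg.max_variants_per_individual]

    # --- extreme minor-frequency / double-peak concordance -------------------
    if (
        len(candidates) == 2
        and cfg.require_direct_seq_concordance
        and clones.total_clones >= cfg.min_clones
        and clones.counts[candidates[1]] <= cfg.extreme_minor_clones
    ):
        diagnostic = {
            i + 1
            for i, (x, y) in enumerate(zip(candidates[0], candidates[1]))
            if x != y
        }
        peaks = clones.double_peaks or frozenset()
        if not diagnostic <= peaks:
            reasons.append(
                "extreme minor-variant frequency without double-peak confirmation"
            )
            return GenotypeCall(
                clones.individual_id, (), True, reasons, artifacts, clones.unit
            )

    return GenotypeCall(
        clones.individual_id, tuple(candidates), False, reasons, artifacts, clones.unit
    )


@dataclass
class PanelCalls:
    calls: list[GenotypeCall]
    cfg: QcConfig

    @property
    def included(self) -> list[GenotypeCall]:
        return [c for c in self.calls if not c.excluded]

    @property
    def variant_set(self) -> set[str]:
        return {v for c in self.included for v in c.variants}

    def genotype_frame(self, name_of: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for c in self.included:
            g = c.genotype
            assert g is not None
            a1, a2 = g
            if name_of:
                a1, a2 = name_of.get(a1, a1), name_of.get(a2, a2)
            rows.append(
                {
                    "individual_id": c.individual_id,
                    "unit": c.unit,
                    "variant1": a1,
                    "variant2": a2,
                }
            )
        return pd.DataFrame(rows)

    def qc_log(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "individual_id": c.individual_id,
                    "unit": c.unit,
                    "excluded": c.excluded,
                    "n_variants": len(c.variants),
                    "reasons": "; ".join(c.reasons),
                }
            )
        return pd.DataFrame(rows)


def call_panel(
    clone_sets: Sequence[CloneSet],
    cfg: QcConfig | None = None,
    known: Iterable[str] = (),
) -> PanelCalls:
    """Two-pass genotyping of a cohort of clone sets.

    Pass 1 derives each individual's validated background: a sequence
    observed with supporting clone counts (>= ``min_support``) in some
    *other* individual cannot be an individual-private PCR artifact.
    Mere recurrence of single clones does not validate — identical
    1-bp errors of a very common allele recur across the cohort.
    Pass 2 calls each individual against its background (plus any
    externally ``known`` variants).
    """
    cfg = cfg or QcConfig()
    supported_in: Counter[str] = Counter()
    for cs in clone_sets:
        for seq, count in cs.counts.items():
            if count >= cfg.min_support:
                supported_in[seq] += 1
    external = set(known)
    calls = []
    for cs in clone_sets:
        background = {
            s
            for s, k in supported_in.items()
            if k >= (2 if cs.counts.get(s, 0) >= cfg.min_support else 1)
        }
        calls.append(call_genotype(cs, frozenset(background | external), cfg))
    return PanelCalls(calls=calls, cfg=cfg)


@dataclass
class CriteriaComparison:
    n_variants_study: int
    n_variants_conservative: int
    n_individuals_study: int
    n_individuals_conservative: int
    removed_variants: dict[str, list[str]]  # variant -> supporting individuals
    only_in_conservative: set[str]

    @property
    def conservative_is_subset(self) -> bool:
        return not self.only_in_conservative

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "criteria": "study",
                "n_variants": self.n_variants_study,
                "n_individuals": self.n_individuals_study,
            },
            {
                "criteria": "conservative",
                "n_variants": self.n_variants_conservative,
                "n_individuals": self.n_individuals_conservative,
            },
        ]
        return pd.DataFrame(rows)


def compare_criteria(
    calls_study: PanelCalls, calls_conservative: PanelCalls
) -> CriteriaComparison:
    """Contrast the study-criteria and conservative-criteria call sets.

    Reports variant and individual counts and, for every variant retained
    only under the study criteria, the individuals that supported it.
    """
    vs = calls_study.variant_set
    vc = calls_conservative.variant_set
    removed = {}
    for variant in sorted(vs - vc):
        removed[variant] = sorted(
            c.individual_id for c in calls_study.included if variant in c.variants
        )
    return CriteriaComparison(
        n_variants_study=len(vs),
        n_variants_conservative=len(vc),
        n_individuals_study=len(calls_study.included),
        n_individuals_conservative=len(calls_conservative.included),
        removed_variants=removed,
        only_in_conservative=vc - vs,
    )


def read_clone_sets(
    clone_dir: str | Path,
    double_peak_file: str | Path | None = None,
    window: tuple[int, int] | None = None,
) -> list[CloneSet]:
    """Read one FASTA of clone reads per individual from a directory.

    File stem is the individual id, optionally ``<unit>__<individual>``.
    ``double_peak_file`` is a delimited table (individual_id, positions)
    with comma-separated 1-based bp positions of chromatogram double
    peaks from direct sequencing.
    """
    peaks: dict[str, frozenset[int]] = {}
    if double_peak_file is not None:
        df = pd.read_csv(double_peak_file, sep=None, engine="python", dtype=str)
        for _, rec in df.iterrows():
            raw = rec.get("positions")
            pos = (
                frozenset(int(x) for x in str(raw).split(",") if str(x).strip())
                if pd.notna(raw) and str(raw).strip()
                else frozenset()
            )
            peaks[rec["individual_id"]] = pos
    sets = []
    for path in sorted(Path(clone_dir).glob("*.fa*")):
        stem = path.stem
        unit, _, indiv = stem.partition("__")
        if not indiv:
            unit, indiv = None, stem
        clones = []
        for rec in SeqIO.parse(str(path), "fasta"):
            s = str(rec.seq).upper()
            if window is not None:
                s = s[window[0] - 1 : window[1]]
            clones.append(s)
        if not clones:
            raise ValueError(f"no clone records in {path}")
        sets.append(
            CloneSet.from_clones(indiv, clones, unit=unit, double_peaks=peaks.get(indiv))
        )
    return sets
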
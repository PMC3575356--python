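"""Synthetic study generator with full ground truth.

Emulates the statistical structure the analysis assumes so that every
pipeline stage is testable without the deposited sequences: a panel of
allotypes with PBR-elevated nonsynonymous divergence generated by a
two-phase (shared trunk + allele-specific tip) mutation model, one
dominant allele shared by all management units plus a Dirichlet tail of
unit-specific rare alleles, an inbreeding-like parameter F that forces
the observed heterozygote deficit (H_o = (1 - F) H_e in expectation),
and per-individual clone sets of 8–22 clones carrying PCR point errors.

Every random draw flows from named integer streams derived from one
seed, and truth records carry enough detail (mutations, frequencies,
true genotypes) to score any stage exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, UnitGenotypeTable, genotype_table_from_individuals, write_alignment
from .allotypes import PbrMask
from .genotyping import CloneSet
from .selection import AA, BASES, CODONS

__all__ = [
    "SynthConfig",
    "simulate_allele_panel",
    "simulate_unit_genotypes",
    "simulate_clone_sets",
    "simulate_study",
    "StudyBundle",
]

_NONSTOP = [c for c in CODONS if AA[c] != "*"]

# stream tags keep the per-stage RNGs independent of one another
_STREAMS = {"panel": 1, "genotypes": 2, "clones": 3}


@dataclass
class SynthConfig:
    """Study-shaped generator settings.

    Defaults mirror the bear survey: 31 allotypes over 89 codons with a
    dominant allele near frequency 0.59 and many rare unit-specific
    alleles, 12 management units with the study's sample sizes, a
    heterozygote deficit around H_o/H_e = 0.65 (F = 0.35), and 8–22
    clones per individual with a per-base PCR error rate of 5e-4.
    """

    seed: int = 0
    n_allotypes: int = 31
    n_codons: int = 89
    pbr_mask: PbrMask | None = None
    w_pbr: float = 6.0  # relative acceptance of nonsynonymous changes at PBR codons
    w_non_pbr: float = 0.6  # and at non-PBR codons (syn changes always accepted)
    trunk_lineages: int = 4
    trunk_mutations: int = 20  # depth of the old lineage; stretches d_TMRCA past 2 x mean d_S
    tip_mutations: float = 3.0  # Poisson mean of allele-specific mutations (+1)
    synonymous_variants: int = 12  # extra variants that differ only synonymously
    dominant_freq: float = 0.59
    rare_concentration: float = 0.35  # Dirichlet alpha of the rare-allele tail
    n_units: int = 12
    individuals_per_unit: tuple[int, ...] = (5, 21, 1, 13, 1, 12, 36, 23, 8, 53, 3, 9)
    drift: float = 0.08  # per-unit frequency perturbation (0 = identical units)
    inbreeding_f: float = 0.35
    clones_min: int = 8
    clones_max: int = 22
    error_rate: float = 5e-4  # per-base PCR error per clone
    amplification_bias: float = 0.0  # shift of the per-clone allele-1 probability
    inject_pseudogene: bool = True
    inject_recombinant: bool = False

    def __post_init__(self) -> None:
        if self.n_allotypes < 2:
            raise ValueError("need at least 2 allotypes")
        if min(self.w_pbr, self.w_non_pbr) < 0:
            raise ValueError("acceptance weights must be non-negative")
        if not 0 <= self.inbreeding_f <= 1:
            raise ValueError("F must be in [0, 1]")
        if not 1 <= self.clones_min <= self.clones_max <= 50:
            raise ValueError("clone range must satisfy 1 <= min <= max <= 50")
        if not 0 <= self.error_rate <= 0.01:
            raise ValueError("error rate outside the plausible PCR range")
        if len(self.individuals_per_unit) != self.n_units:
            raise ValueError("individuals_per_unit length must equal n_units")

    def mask(self) -> PbrMask:
        return self.pbr_mask or PbrMask.default()

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % 2**31, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# allele panel
# ---------------------------------------------------------------------------


def _mutate(
    seq: list[str],
    rng: np.random.Generator,
    pbr: set[int],
    cfg: SynthConfig,
    allow_stop: bool = False,
    force_nonsyn: bool | None = None,
) -> dict | None:
    """Propose-and-accept one point mutation in place; returns a truth record."""
    m = max(cfg.w_pbr, cfg.w_non_pbr, 1.0)
    for _ in range(500):
        c = int(rng.integers(cfg.n_codons))
        pos = int(rng.integers(3))
        codon = seq[c]
        base = BASES[int(rng.integers(4))]
        if base == codon[pos]:
            continue
        new = codon[:pos] + base + codon[pos + 1 :]
        if AA[new] == "*" and not allow_stop:
            continue
        syn = AA[new] == AA[codon]
        if force_nonsyn is True and syn:
            continue
        if force_nonsyn is False and not syn:
            continue
        if force_nonsyn is None:
            # relative acceptance: synonymous 1, nonsynonymous w_pbr / w_non_pbr
            weight = 1.0 if syn else (cfg.w_pbr if (c + 1) in pbr else cfg.w_non_pbr)
            if rng.random() > weight / m:
                continue
        seq[c] = new
        return {
            "codon": c + 1,
            "position": pos + 1,
            "from": codon,
            "to": new,
            "synonymous": syn,
            "pbr": (c + 1) in pbr,
        }
    return None


def simulate_allele_panel(cfg: SynthConfig) -> tuple[CodonAlignment, dict]:
    """Generate the variant panel and its truth record.

    Trunk lineages diverge deeply from a random stop-free ancestor; each
    allotype hangs off a trunk with its own tip mutations.  Nonsynonymous
    changes are accepted with relative weight ``w_pbr`` at PBR codons and
    ``w_non_pbr`` elsewhere (synonymous changes always pass), so
    ``w_pbr = w_non_pbr = 1`` is the neutral null.  Optionally exactly
    one variant carries a premature stop (pseudogene) and one is a
    beta-sheet/alpha-helix crossover of two diverged trunks.
    """
    rng = cfg.rng("panel")
    mask = cfg.mask()
    pbr = set(mask.codon_indices(cfg.n_codons))

    ancestor = [_NONSTOP[i] for i in rng.integers(len(_NONSTOP), size=cfg.n_codons)]
    mutations: list[dict] = []

    # trunk 0 is an old minor lineage (full depth); the rest split recently
    # (quarter depth), so the deepest pairwise distance well exceeds twice
    # the mean — the genealogy shape of long-lived balanced allelic lines.
    trunks: list[list[str]] = []
    for t in range(cfg.trunk_lineages):
        depth = cfg.trunk_mutations if t == 0 else max(cfg.trunk_mutations // 4, 1)
        seq = list(ancestor)
        for _ in range(depth):
            rec = _mutate(seq, rng, pbr, cfg)
            if rec:
                rec["lineage"] = f"trunk{t}"
                mutations.append(rec)
        trunks.append(seq)

    n_deep = max(2, cfg.n_allotypes // 10)  # allotypes riding the old lineage
    peptides_seen: set[str] = set()
    variants: dict[str, str] = {}
    allotype_seqs: list[list[str]] = []
    for i in range(cfg.n_allotypes):
        if i >= cfg.n_allotypes - n_deep:  # rare allotypes ride the old lineage
            trunk = trunks[0]
        else:
            trunk = trunks[1 + i % (cfg.trunk_lineages - 1)]
        for _ in range(50):
            seq = list(trunk)
            n_tip = int(rng.poisson(cfg.tip_mutations)) + 1
            recs = []
            for _ in range(n_tip):
                rec = _mutate(seq, rng, pbr, cfg)
                if rec:
                    recs.append(rec)
            pep = "".join(AA[c] for c in seq)
            if pep not in peptides_seen:
                break
        peptides_seen.add(pep)
        name = f"Sim-DQB*{i + 1:02d}01"
        for rec in recs:
            rec["lineage"] = name
        mutations.extend(recs)
        variants[name] = "".join(seq)
        allotype_seqs.append(seq)

    # synonymous-only sister variants (dominant allotype gets the most)
    allotype_pool = rng.choice(
        cfg.n_allotypes, size=cfg.synonymous_variants, p=_syn_weights(cfg.n_allotypes)
    )
    suffix = {i: 1 for i in range(cfg.n_allotypes)}
    for a in allotype_pool:
        a = int(a)
        for _ in range(50):
            seq = list(allotype_seqs[a])
            recs = []
            for _ in range(int(rng.integers(1, 3))):
                rec = _mutate(seq, rng, pbr, cfg, force_nonsyn=False)
                if rec:
                    recs.append(rec)
            new_seq = "".join(seq)
            if recs and new_seq not in variants.values():
                break
        else:
            continue
        suffix[a] += 1
        name = f"Sim-DQB*{a + 1:02d}{suffix[a]:02d}"
        for rec in recs:
            rec["lineage"] = name
        mutations.extend(recs)
        variants[name] = new_seq

    truth: dict = {
        "ancestor": "".join(ancestor),
        "mutations": mutations,
        "pseudogene": None,
        "recombinant": None,
        "config": {
            k: v for k, v in asdict(cfg).items() if k != "pbr_mask"
        },
    }

    if cfg.inject_pseudogene:
        seq = list(allotype_seqs[0])
        stop_sites = [
            (c, pos, b)
            for c in range(cfg.n_codons)
            for pos in range(3)
            for b in BASES
            if b != seq[c][pos]
            and AA[seq[c][:pos] + b + seq[c][pos + 1 :]] == "*"
        ]
        c, pos, b = stop_sites[int(rng.integers(len(stop_sites)))]
        seq[c] = seq[c][:pos] + b + seq[c][pos + 1 :]
        name = f"Sim-DQB*{cfg.n_allotypes + 1:02d}01"
        variants[name] = "".join(seq)
        truth["pseudogene"] = name

    if cfg.inject_recombinant:
        a, b = trunks[0], trunks[-1]
        cross = cfg.n_codons // 2
        name = f"Sim-DQB*{cfg.n_allotypes + 2:02d}01"
        variants[name] = "".join(a[:cross] + b[cross:])
        truth["recombinant"] = {"variant": name, "crossover_codon": cross + 1}

    return CodonAlignment(variants), truth


def _syn_weights(k: int) -> np.ndarray:
    # the dominant allotype carries most synonymous sister variants
    w = np.ones(k)
    w[0] = k
    return w / w.sum()


# ---------------------------------------------------------------------------
# unit genotypes
# ---------------------------------------------------------------------------


def simulate_unit_genotypes(
    panel: CodonAlignment, cfg: SynthConfig, truth_panel: dict | None = None
) -> tuple[UnitGenotypeTable, dict]:
    """Draw per-unit allele frequencies and per-individual genotypes.

    The global frequency vector gives the first variant the dominant
    frequency and spreads the rest over a Dirichlet tail (singletons
    abound at low concentration).  Unit vectors are Dirichlet
    perturbations around the global one with spread ``drift``; genotypes
    follow the inbreeding model P(hom i) = p_i^2 + F p_i (1 - p_i).
    """
    rng = cfg.rng("genotypes")
    pseudo = (truth_panel or {}).get("pseudogene")
    coding = [v for v in panel.ids if v != pseudo]
    k = len(coding)
    tail = rng.dirichlet(np.full(k - 1, cfg.rare_concentration))
    global_freq = np.concatenate([[cfg.dominant_freq], (1 - cfg.dominant_freq) * tail])

    units = [f"U{i + 1:02d}" for i in range(cfg.n_units)]
    unit_freqs: dict[str, np.ndarray] = {}
    rows = []
    for unit, n_ind in zip(units, cfg.individuals_per_unit):
        if cfg.drift > 0:
            alpha = np.maximum(global_freq / cfg.drift, 1e-8)
            p = rng.dirichlet(alpha)
        else:
            p = global_freq.copy()
        unit_freqs[unit] = p
        for j in range(n_ind):
            a1 = int(rng.choice(k, p=p))
            a2 = a1 if rng.random() < cfg.inbreeding_f else int(rng.choice(k, p=p))
            rows.append(
                {
                    "individual_id": f"{unit}-{j + 1:03d}",
                    "unit": unit,
                    "variant1": coding[a1],
                    "variant2": coding[a2],
                }
            )
    genotypes = pd.DataFrame(rows)
    table = genotype_table_from_individuals(genotypes)
    # keep unit columns in simulation order
    table.counts = table.counts.reindex(columns=units, fill_value=0)
    truth = {
        "global_frequencies": dict(zip(coding, global_freq.tolist())),
        "unit_frequencies": {u: dict(zip(coding, p.tolist())) for u, p in unit_freqs.items()},
        "inbreeding_f": cfg.inbreeding_f,
        "drift": cfg.drift,
    }
    return table, truth


# ---------------------------------------------------------------------------
# clone sets
# ---------------------------------------------------------------------------


def simulate_clone_sets(
    genotypes: pd.DataFrame, panel: CodonAlignment, cfg: SynthConfig
) -> tuple[list[CloneSet], dict]:
    """Clone each individual's two true alleles with PCR point errors.

    Clone counts are uniform in ``[clones_min, clones_max]``; each clone
    derives from allele 1 with probability 0.5 + amplification_bias and
    every base mutates independently with probability ``error_rate``
    (yielding the near-duplicate 1–2 bp artifact sequences the QC rules
    target).  Double-peak records list the sites where the true alleles
    differ, as direct sequencing of the uncloned product would show.
    """
    rng = cfg.rng("clones")
    length = panel.length
    sets: list[CloneSet] = []
    truth: dict[str, dict] = {}
    q = float(np.clip(0.5 + cfg.amplification_bias, 0.0, 1.0))
    for _, rec in genotypes.iterrows():
        a1, a2 = panel[rec["variant1"]], panel[rec["variant2"]]
        n_clones = int(rng.integers(cfg.clones_min, cfg.clones_max + 1))
        clones = []
        for _ in range(n_clones):
            src = a1 if rng.random() < q else a2
            n_err = rng.binomial(length, cfg.error_rate)
            if n_err:
                s = list(src)
                for pos in rng.choice(length, size=n_err, replace=False):
                    s[pos] = rng.choice([b for b in BASES if b != s[pos]])
                src = "".join(s)
            clones.append(src)
        peaks = frozenset(
            i + 1 for i, (x, y) in enumerate(zip(a1, a2)) if x != y
        )
        sets.append(
            CloneSet.from_clones(
                rec["individual_id"], clones, unit=rec["unit"], double_peaks=peaks
            )
        )
        truth[rec["individual_id"]] = {
            "genotype": sorted((rec["variant1"], rec["variant2"])),
            "n_clones": n_clones,
        }
    return sets, truth


# ---------------------------------------------------------------------------
# complete bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    alignment: CodonAlignment
    table: UnitGenotypeTable
    clone_sets: list[CloneSet]
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, out / "variants.fasta")
        self.table.to_tsv(out / "unit_table.tsv")
        assert self.table.genotypes is not None
        self.table.genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        clone_dir = out / "clones"
        clone_dir.mkdir(exist_ok=True)
        peak_rows = []
        for cs in self.clone_sets:
            path = clone_dir / f"{cs.unit}__{cs.individual_id}.fasta"
            with open(path, "w") as fh:
                i = 0
                for seq, count in cs.counts.items():
                    for _ in range(count):
                        i += 1
                        fh.write(f">{cs.individual_id}_clone{i:02d}\n{seq}\n")
            peak_rows.append(
                {
                    "individual_id": cs.individual_id,
                    "positions": ",".join(map(str, sorted(cs.double_peaks or []))),
                }
            )
        pd.DataFrame(peak_rows).to_csv(out / "double_peaks.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_study(cfg: SynthConfig | None = None) -> StudyBundle:
    """Generate a complete synthetic study: panel, genotypes and clones."""
    cfg = cfg or SynthConfig()
    panel, truth_panel = simulate_allele_panel(cfg)
    table, truth_geno = simulate_unit_genotypes(panel, cfg, truth_panel)
    assert table.genotypes is not None
    clones, truth_clones = simulate_clone_sets(table.genotypes, panel, cfg)
    return StudyBundle(
        alignment=panel,
        table=table,
        clone_sets=clones,
        truth={"panel": truth_panel, "genotypes": truth_geno, "clones": truth_clones},
    )
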
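"""End-to-end orchestration: QC → allotypes/PBR → selection → popgen → recombination.

A single YAML config names the inputs (alignment, unit table, optional
per-individual genotypes and clone directory) and the statistical
settings; :func:`run_pipeline` executes every stage whose inputs are
present, writes table-shaped CSV outputs, and records provenance
(seeds, versions, and an explicit "not computed" reason for every
skipped stage).  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import (
    CodonAlignment,
    UnitGenotypeTable,
    read_alignment,
    read_individual_genotypes,
    read_unit_table,
)
from .allotypes import (
    PbrMask,
    classify_pbr_types,
    heterozygote_pbr_mismatch,
    nj_pbr_tree,
    polymorphic_site_summary,
    site_variability,
    translate_and_flag,
)
from .genotyping import QcConfig, call_panel, compare_criteria, read_clone_sets
from .popgen import (
    fst_weir_cockerham,
    gst_prime_and_jost_d,
    heterozygosity,
    hwe_test,
    kst,
    observed_heterozygosity,
    regional_aggregate,
)
from .recombination import RegionSplit, binomial_region_test
from .selection import SelectionConfig, kb_statistic, partitioned_dnds, pi_s, tmrca

__all__ = ["PipelineConfig", "run_pipeline"]


def _derived_seed(master: int, index: int) -> int:
    return (master * 1_000_003 + index * 7919 + 17) % 2**31


@dataclass
class PipelineConfig:
    outdir: str = "mhcdiv_out"
    alignment: str | None = None
    window: tuple[int, int] | None = None
    unit_table: str | None = None
    genotypes: str | None = None
    clone_dir: str | None = None
    double_peaks: str | None = None
    pbr_mask: str | None = None
    unit_regions: str | None = None
    boundary_beta: int = 53
    seed: int = 0
    permutations: int = 1000
    hwe_reps: int = 100_000
    min_individuals: int = 10  # units entering diversity/differentiation stats
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    qc: QcConfig = field(default_factory=QcConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sel = SelectionConfig(**doc.pop("selection", {}))
        qc = QcConfig(**doc.pop("qc", {}))
        window = doc.pop("window", None)
        if window is not None:
            window = (int(window[0]), int(window[1]))
        return cls(selection=sel, qc=qc, window=window, **doc)

    def load_mask(self) -> PbrMask:
        return PbrMask.from_yaml(self.pbr_mask) if self.pbr_mask else PbrMask.default()

    def load_regions(self) -> dict[str, str]:
        if self.unit_regions:
            with open(self.unit_regions) as fh:
                doc = yaml.safe_load(fh)
        else:
            from importlib import resources

            with resources.files("mhcdiv.data").joinpath("unit_regions.yaml").open() as fh:
                doc = yaml.safe_load(fh)
        return {u: region for region, units in doc.items() for u in units}


def _unit_sequences(table: UnitGenotypeTable, aln: CodonAlignment, unit: str) -> list[str]:
    seqs = []
    for v, c in table.unit_allele_counts(unit).items():
        if v in aln:
            seqs.extend([aln[v]] * c)
    return seqs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage whose inputs exist; return the provenance record."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    prov: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stages": status,
        "inputs": {
            k: getattr(cfg, k)
            for k in ("alignment", "unit_table", "genotypes", "clone_dir")
        },
    }

    aln = read_alignment(cfg.alignment, cfg.window) if cfg.alignment else None
    table = read_unit_table(cfg.unit_table) if cfg.unit_table else None
    genotypes = read_individual_genotypes(cfg.genotypes) if cfg.genotypes else None
    if table is not None and genotypes is not None:
        table.genotypes = genotypes
        table.validate()
    mask = cfg.load_mask()

    # --- genotyping QC ------------------------------------------------------
    if cfg.clone_dir:
        clone_sets = read_clone_sets(cfg.clone_dir, cfg.double_peaks, window=None)
        known = frozenset(aln[v] for v in aln.ids) if aln else frozenset()
        name_of = {aln[v]: v for v in aln.ids} if aln else {}
        results = {}
        for mode in ("study", "conservative"):
            qc_cfg = QcConfig(**{**vars(cfg.qc), "mode": mode})
            calls = call_panel(clone_sets, qc_cfg, known=known)
            calls.qc_log().to_csv(out / f"qc_log_{mode}.tsv", sep="\t", index=False)
            calls.genotype_frame(name_of).to_csv(
                out / f"genotypes_{mode}.tsv", sep="\t", index=False
            )
            results[mode] = calls
        comparison = compare_criteria(results["study"], results["conservative"])
        comparison.to_frame().to_csv(out / "criteria_comparison.tsv", sep="\t", index=False)
        with open(out / "criteria_removed_variants.json", "w") as fh:
            json.dump(comparison.removed_variants, fh, indent=1)
        status["qc"] = "computed"
    else:
        status["qc"] = "not computed: no clone_dir input"

    # --- allotypes / PBR ----------------------------------------------------
    panel = None
    if aln is not None:
        panel = translate_and_flag(aln)
        var = site_variability(panel, mask)
        var.to_csv(out / "site_variability.tsv", sep="\t")
        with open(out / "allotype_summary.json", "w") as fh:
            json.dump(
                {
                    "n_variants": len(aln),
                    "n_allotypes": panel.n_allotypes,
                    "pseudogenes": sorted(panel.pseudogenes),
                    "n_pbr_types": len(classify_pbr_types(panel, mask)),
                    **polymorphic_site_summary(var),
                },
                fh,
                indent=1,
            )
        peps = panel.allotype_peptides()
        if len(set(peps.values())) >= 3:
            (out / "pbr_nj_tree.nwk").write_text(
                nj_pbr_tree(
                    {
                        a: "".join(
                            p[i - 1] for i in mask.codon_indices(aln.n_codons)
                        )
                        for a, p in peps.items()
                    }
                )
                + "\n"
            )
        if genotypes is not None:
            pairs = [
                (r["variant1"], r["variant2"])
                for _, r in genotypes.iterrows()
                if r["variant1"] in panel.peptides and r["variant2"] in panel.peptides
            ]
            mm, het = heterozygote_pbr_mismatch(
                pairs, panel, classify_pbr_types(panel, mask)
            )
            with open(out / "pbr_heterozygote_mismatch.json", "w") as fh:
                json.dump({"mismatched": mm, "heterozygotes": het}, fh)
        status["allotypes"] = "computed"
    else:
        status["allotypes"] = "not computed: no alignment input"

    # --- selection ----------------------------------------------------------
    if panel is not None and len(set(panel.coding_variants)) >= 2:
        sel_cfg = SelectionConfig(
            **{**vars(cfg.selection), "seed": _derived_seed(cfg.seed, 1)}
        )
        coding = aln.subset(panel.coding_variants)
        parts = partitioned_dnds(coding, mask, sel_cfg)
        pd.DataFrame([vars(p) for p in parts.values()]).to_csv(
            out / "selection_partitions.tsv", sep="\t", index=False
        )
        kb, lineages = kb_statistic(coding, mask)
        d_max, years, ratio = tmrca(coding, sel_cfg)
        sel_summary = {
            "kb": kb,
            "kb_lineages": lineages,
            "d_tmrca": d_max,
            "tmrca_years": years,
            "tmrca_ratio_to_mean": ratio,
        }
        if table is not None:
            pis = {}
            for unit in table.units:
                counts = {
                    v: c for v, c in table.unit_allele_counts(unit).items() if v in coding
                }
                if sum(counts.values()) >= 2:
                    pis[unit] = pi_s(coding, counts, sel_cfg)
            overall = {
                v: int(c)
                for v, c in table.variant_totals().items()
                if v in coding and c > 0
            }
            pis["overall"] = pi_s(coding, overall, sel_cfg)
            sel_summary["pi_s"] = pis
        with open(out / "selection_summary.json", "w") as fh:
            json.dump(sel_summary, fh, indent=1)
        status["selection"] = "computed"
    else:
        status["selection"] = "not computed: need an alignment with >= 2 coding variants"

    # --- per-unit diversity and differentiation ------------------------------
    if table is not None:
        rows = []
        geno_by_unit = {}
        if table.genotypes is not None:
            for unit, grp in table.genotypes.groupby("unit"):
                geno_by_unit[unit] = list(zip(grp["variant1"], grp["variant2"]))
        for i, unit in enumerate(table.units):
            counts = table.unit_allele_counts(unit)
            if not counts:
                continue
            he, se = heterozygosity(
                counts, bootstrap_reps=1000, seed=_derived_seed(cfg.seed, 100 + i)
            )
            row = {
                "unit": unit,
                "n_individuals": sum(counts.values()) // 2,
                "n_alleles": len(counts),
                "He": he,
                "He_se": se,
            }
            pairs = geno_by_unit.get(unit)
            if pairs:
                row["Ho"] = observed_heterozygosity(pairs)
                hwe = hwe_test(
                    pairs, mc_reps=cfg.hwe_reps, seed=_derived_seed(cfg.seed, 200 + i)
                )
                row["hwe_p"] = hwe.p_exact
                row["hwe_p_deficit"] = hwe.p_deficit
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)

        big_units = [
            u
            for u in table.units
            if sum(table.unit_allele_counts(u).values()) // 2 >= cfg.min_individuals
        ]
        if len(big_units) >= 2:
            pair_rows = []
            for a_i in range(len(big_units)):
                for b_i in range(a_i + 1, len(big_units)):
                    u1, u2 = big_units[a_i], big_units[b_i]
                    row = {"unit1": u1, "unit2": u2}
                    est = gst_prime_and_jost_d(
                        [table.unit_allele_counts(u1), table.unit_allele_counts(u2)]
                    )
                    row["gst_prime"] = est.g_st_prime
                    row["jost_d"] = est.jost_d
                    if aln is not None:
                        seqs = [_unit_sequences(table, aln, u) for u in (u1, u2)]
                        if all(len(s) >= 2 for s in seqs):
                            row["kst"], row["kst_p"] = kst(
                                seqs,
                                permutations=cfg.permutations,
                                seed=_derived_seed(cfg.seed, 300 + a_i * 50 + b_i),
                            )
                    if geno_by_unit.get(u1) and geno_by_unit.get(u2):
                        row["fst"], row["fst_p"] = fst_weir_cockerham(
                            [geno_by_unit[u1], geno_by_unit[u2]],
                            permutations=cfg.permutations,
                            seed=_derived_seed(cfg.seed, 400 + a_i * 50 + b_i),
                        )
                    pair_rows.append(row)
            pair_df = pd.DataFrame(pair_rows)
            pair_df.to_csv(out / "differentiation.tsv", sep="\t", index=False)
            region_map = cfg.load_regions()
            stats = [
                c for c in ("kst", "fst", "gst_prime", "jost_d") if c in pair_df.columns
            ]
            if stats and any(u in region_map for u in big_units):
                regional_aggregate(pair_df, region_map, stats).to_csv(
                    out / "differentiation_regional.tsv", sep="\t"
                )
            status["differentiation"] = "computed"
        else:
            status["differentiation"] = (
                f"not computed: fewer than 2 units with >= {cfg.min_individuals} individuals"
            )
        status["diversity"] = "computed"
    else:
        status["diversity"] = "not computed: no unit table input"
        status["differentiation"] = "not computed: no unit table input"

    # --- recombination test -------------------------------------------------
    if aln is not None and len(aln) >= 2:
        split = RegionSplit(boundary_beta=cfg.boundary_beta)
        binomial_region_test(aln, split, scope="pooled").to_csv(
            out / "recombination_pooled.tsv", sep="\t", index=False
        )
        binomial_region_test(aln, split, scope="per-pair").to_csv(
            out / "recombination_pairs.tsv", sep="\t", index=False
        )
        status["recombination"] = "computed"
    else:
        status["recombination"] = "not computed: need an alignment with >= 2 variants"

    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, default=str)
    return prov
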
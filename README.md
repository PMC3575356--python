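# mhcdiv

Analysis toolkit for MHC class II **DQB exon-2** diversity surveys of wild
mammal populations — built around the Japanese black bear (*Ursus thibetanus
japonicus*) survey design: a 270-bp exon-2 amplicon (267 bp / 89 codons
analysed, residues β6–β94 in human DRβ numbering) typed by cloning PCR
products from bears sampled across conservation and management units.

It is aimed at conservation geneticists who need, from a single package:

* **Clone-based genotyping QC** — call each individual's one or two alleles
  from 8–22 sequenced clones, discard PCR artifacts under either a permissive
  *study* criterion or the classic *conservative* criterion (a rare sequence
  seen in one individual alone and differing by fewer than 3 bp from another
  sequence of the same PCR product is an artifact), and audit every exclusion.
* **Allotype / PBR accounting** — translate variants, flag premature-stop
  pseudogenes, group variants into allotypes and allotypes into
  peptide-binding-residue (PBR) types, Wu–Kabat variability plots, and a
  neighbor-joining tree on pairwise amino-acid differences of the PBR.
* **Balancing-selection statistics** — modified Nei–Gojobori *d*N/*d*S with
  Jukes–Cantor correction, partitioned into PBR / non-PBR / entire region
  with codon-bootstrap standard errors; the mean pairwise count of
  nonsynonymous PBR differences *K*B; and a molecular-clock TMRCA from the
  maximum pairwise synonymous distance, *T* = *d*max / 2μ.
* **Population statistics** — unbiased expected heterozygosity
  *H*e = (2n/(2n−1))(1 − Σ*p*²), observed heterozygosity, exact
  Hardy–Weinberg tests (enumeration or Monte-Carlo) with a one-sided
  heterozygote-deficit variant, synonymous nucleotide diversity πS, and
  pairwise differentiation by Hudson's *K*ST, Weir–Cockerham θ (*F*ST),
  Hedrick's *G*′ST and Jost's *D* with permutation significance.
* **Recombination screen** — an exact binomial test of whether nucleotide
  differences concentrate in the β-sheet versus α-helix half of exon 2.
* **A synthetic-study generator** with complete ground truth (one dominant
  allele plus many unit-specific rare alleles, PBR-elevated nonsynonymous
  divergence, an inbreeding-like heterozygote deficit, clone sets with PCR
  point errors), so every stage is testable without archival sequence
  downloads.

The published per-unit allele-count table of the bear survey ships with the
package (`mhcdiv/data/unit_table.tsv`), as do an editable PBR mask
(human-DR contact positions restricted to β6–β94) and the east/west unit
grouping.

## Worked example

```python
from importlib import resources
from mhcdiv import (SelectionConfig, SynthConfig, PbrMask, heterozygosity,
                    kb_statistic, partitioned_dnds, read_unit_table,
                    simulate_allele_panel, tmrca, translate_and_flag)

# published allele counts: expected heterozygosity of one management unit
table = read_unit_table(resources.files("mhcdiv.data").joinpath("unit_table.tsv"))
he, _ = heterozygosity(table.unit_allele_counts("NCA"))
print(f"NCA He = {he:.2f}")

# synthetic study-shaped panel: 31 allotypes, 44 variants, one pseudogene
aln, truth = simulate_allele_panel(SynthConfig(seed=1))
panel = translate_and_flag(aln)
print(f"{len(aln)} variants -> {panel.n_allotypes} allotypes "
      f"+ {len(panel.pseudogenes)} pseudogene")

mask = PbrMask.default()
coding = aln.subset(panel.coding_variants)
cfg = SelectionConfig(seed=0, bootstrap_reps=200)
parts = partitioned_dnds(coding, mask, cfg)
for name in ("pbr", "non_pbr", "entire"):
    p = parts[name]
    print(f"{name:8s} dN/dS = {p.ratio:.2f}  (dN = {p.d_n:.3f} +/- {p.se_d_n:.3f})")
kb, lineages = kb_statistic(coding, mask)
d_max, years, ratio = tmrca(coding, cfg)
print(f"K_B = {kb:.1f} (~{lineages} allelic lineages)")
print(f"d_TMRCA = {d_max:.3f} -> {years / 1e6:.1f} MY; d_TMRCA / mean d_S = {ratio:.1f}")
```

prints

```
NCA He = 0.85
44 variants -> 31 allotypes + 1 pseudogene
pbr      dN/dS = 6.09  (dN = 0.206 +/- 0.029)
non_pbr  dN/dS = 0.77  (dN = 0.027 +/- 0.007)
entire   dN/dS = 2.23  (dN = 0.077 +/- 0.009)
K_B = 10.5 (~10 allelic lineages)
d_TMRCA = 0.109 -> 15.5 MY; d_TMRCA / mean d_S = 3.2
```

The NCA heterozygosity comes straight from the shipped count table.  The
selection block runs on a synthetic panel whose defaults mirror the bear
survey: nonsynonymous divergence concentrated in the PBR (*d*N/*d*S well
above 1 there, below 1 elsewhere), roughly ten functionally distinct
allelic lineages, and a deepest synonymous split more than twice the mean —
the genealogy shape of long-lived balanced allelic lineages.

## Command line

```bash
mhcdiv simulate --seed 7 --outdir synth/        # full synthetic bundle + truth.json
mhcdiv run-all pipeline.yaml                    # QC -> allotypes -> selection -> popgen -> recombination
mhcdiv qc / allotype / selection / popstats / recomb pipeline.yaml
```

`pipeline.yaml` names the inputs (alignment FASTA, unit table, per-individual
genotypes, clone directory) and settings; every stage writes table-shaped
TSV/JSON outputs plus a provenance record, and stages whose inputs are
missing are skipped with an explicit reason.  Reruns with the same seed are
byte-identical.

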
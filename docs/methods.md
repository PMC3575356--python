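# Methods

This note records the models, estimators, numerical conventions and design
choices behind `mhcdiv`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and the analysis window

Inputs are pre-aligned, gap-free nucleotide sequences of the DQB exon-2
amplicon.  Analyses use the first 267 bp of the 270-bp amplicon — 89
complete codons — dropping the trailing partial codon.  All coordinates are
1-based inclusive; codon 1 is reported as residue β6 of the human DRβ chain
(`beta = codon + 5`), matching how class II exon-2 positions are cited in
the MHC literature.

## PBR mask

The peptide-binding residues are a configurable set of β-position labels.
The default (`mhcdiv/data/pbr_mask.yaml`) is the β-chain antigen-contact
set of the human DR crystal structure restricted to β6–β94 (27 positions:
β9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67, 68, 70,
71, 74, 78, 81, 82, 85, 86, 89, 90).  Published class II studies differ in
exactly which contact positions they count, so every statistic takes the
mask as a parameter and per-mask site tallies are reported rather than
asserted.

## Genotyping QC

Each individual is typed from the distinct sequences among its 8–22 clones
(configurable `min_clones`, default 8; at most 2 variants per individual).

* A sequence is a **candidate allele** when it carries at least
  `min_support` clones (default 2), or matches a variant validated outside
  the individual.  Validation requires *supported* observation elsewhere:
  a sequence seen with ≥ `min_support` clones in some other individual.
  Mere recurrence of single clones does not validate, because identical
  1-bp PCR errors of a very common allele recur across a cohort.
* **Conservative criterion**: additionally, a minor-variant sequence seen
  in this individual alone and within Hamming distance ≤ 2 ("differs by
  less than 3 bp") of a *better-supported* sequence in the same clone set
  is a PCR artifact.  The distance is compared only against sequences with
  more clones — artifacts derive from commoner templates, and comparing
  against rarer sequences would let an allele's own error derivative
  disqualify it.
* **Exclusions** (never guesses): more than two candidates with
  substantial support; tied clone counts at the genotype boundary; or, when
  direct-sequencing concordance is required, an extreme minor-variant
  frequency (≤ 1 clone by default) without chromatogram double peaks at
  every site where the two candidate alleles differ.

Both criteria run side by side in the pipeline; the conservative variant
set is provably a subset of the study set on the same input, and every
discarded sequence and excluded individual is written to a QC log.

## Modified Nei–Gojobori distances

Potential synonymous/nonsynonymous sites per codon: each of the three
positions contributes one site, split by the weighted fraction of
single-base changes that are synonymous, with transitions weighted by the
transition/transversion bias *R* (default 1.58, the ML estimate for the
bear exon-2 data) and transversions by 1.  Changes creating a stop codon
are excluded and the remaining weights renormalised, so site counts are
additive across partitions: N(PBR) + N(non-PBR) = N(entire), for both
classes.

Observed differences between two codons are averaged over all
minimal-length mutational pathways with equal weight; pathways passing
through a stop codon are excluded (if every pathway is blocked, all are
used — this never occurs for sense-codon pairs differing at ≤ 3 sites in
practice).  Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as +∞ with an explicit
saturation flag, never a silent NaN, and saturated pairs are excluded from
means only when configured.

The partitioned statistic removes identical duplicate sequences first,
averages d_N and d_S over all unordered variant pairs, and reports the
**ratio of means** (mean d_N / mean d_S), the convention of the standard
counting-method software, not the mean of per-pair ratios.  Standard
errors come from resampling codons with replacement within each partition
(1 000 replicates by default; the entire-region bootstrap is stratified
into PBR and non-PBR strata so partition sizes are preserved).

*K*B is the mean pairwise **count** of nonsynonymous differences at PBR
codons — pathway-averaged raw counts, no per-site scaling and no
multiple-hit correction, since it estimates a number of substitutions, not
a rate.  Its rounded value approximates the number of functionally
distinct allelic lineages.  πS is the frequency-weighted mean pairwise
JC-corrected synonymous distance (Σᵢⱼ pᵢpⱼ dS(i,j)); an unweighted mode
over distinct variants is provided because published tables do not always
state which convention they use.

TMRCA: the maximum pairwise synonymous distance d_max estimates the
deepest split; with a neutral synonymous rate μ (default 3.5 × 10⁻⁹ per
site per year) the age is d_max / 2μ, two lineages accumulating
substitutions independently.  The ratio d_max / mean d_S is reported
against its neutral-panmictic expectation of 2; substantially larger
values indicate old population structure or long-lived balanced lineages.

## Population statistics

* **H_e**: unbiased estimator (2n/(2n−1))(1 − Σp²) from allele counts;
  SE by multinomial bootstrap of the 2n alleles.
* **Exact HWE test**: conditional probability of the genotype table given
  allele counts, P ∝ n! Πaᵢ! 2^h / (2n)! Πnᵢⱼ!.  Complete enumeration of
  tables for ≤ 3 alleles; otherwise a Monte-Carlo exact test (default 10⁵
  shuffles of the allele vector into random pairings, add-one corrected).
  Both a two-sided p (tables no more probable than observed) and a
  one-sided heterozygote-deficit p (tables with ≤ observed heterozygotes)
  are reported — the deficit direction is the one of biological interest
  when H_o < H_e.  Exact p-values on discrete tables are conservative:
  under the null they are stochastically ≥ uniform, which is what the
  calibration tests assert.
* **K_ST** = 1 − K_S/K_T with K_S the sample-size-weighted mean
  within-population pairwise difference and K_T the pooled mean;
  significance by permuting sequences among populations (default 1 000).
  An all-identical input returns 0 with p = 1.
* **F_ST**: multi-allelic Weir–Cockerham θ, per-allele variance components
  summed over alleles; permutation p by shuffling individuals among
  populations.  Slightly negative estimates are legitimate and reported
  as computed (never truncated), as are negative K_ST and D.
* **G′_ST and Jost's D**: nearly-unbiased estimators with harmonic-mean
  sample size ñ (individuals): H_S,est = 2ñ/(2ñ−1)·H_S,
  H_T,est = H_T + H_S,est/(2ñk); then G′_ST = G_ST(k−1+H_S)/[(k−1)(1−H_S)]
  and D = k/(k−1)·(H_T,est−H_S,est)/(1−H_S,est).  H_S = 1 exactly makes
  the standardisation undefined and is flagged.  Both hit 1 at reciprocal
  fixation and ≈ 0 (possibly slightly negative) for identical populations.
* **Regional averages** are arithmetic means of the pairwise statistics
  over within-region unit pairs, with the unit→region map configurable
  (default groups the small Kii-Hanto and Shikoku units with western
  Japan).

## Recombination region test

Under clonal evolution the s nucleotide differences between two variants
fall into the β-sheet region (default β6–β52; boundary configurable) as
s_A ~ Binomial(s, L_A/L).  The test is exact and two-sided with no normal
approximation (s ≤ ~60 here), applied per variant pair with Bonferroni
correction, or pooled over segregating sites; s = 0 gives p = 1 by
convention.  The default boundary follows the canonical β1-domain
secondary structure (sheet floor then helix wall); it is a config value,
not a claim about the exact crystallographic boundary.

## Wu–Kabat variability and PBR types

Variability at a residue position is V = k·N/n_max (k distinct residues,
N allotypes, n_max the modal residue count); V = 1 iff invariant.
Allotypes sharing the PBR-restricted peptide form one PBR type.  The NJ
tree on PBR peptides uses the count-of-differences distance and classic
neighbor joining with two determinism conventions: Q-criterion ties join
the lexicographically smallest label pair, and negative branch lengths are
clamped to zero with the deficit moved to the sister branch.  Identical
peptides are collapsed before tree building.

## Synthetic-data generator

The generator emulates the statistical structure of the survey, not its
history.  Defaults are the study conditions: 31 allotypes over 89 codons
(44 variants once synonymous sisters and one pseudogene are added), a
dominant allele at frequency 0.59 with a low-concentration Dirichlet tail
of rare alleles (singletons abound), 12 units with the survey's sample
sizes (5, 21, 1, 13, 1, 12, 36, 23, 8, 53, 3, 9), an inbreeding-like
parameter F = 0.35 (so E[H_o] = (1−F)·H_e ≈ 0.65·H_e, the observed
deficit), per-unit Dirichlet drift 0.08, 8–22 clones per individual and a
per-base PCR error rate of 5 × 10⁻⁴ chosen as a realistic proofread-PCR
figure.

Mutations are placed on a two-phase genealogy: trunk lineages diverge from
a random stop-free ancestor — one old minor lineage at full depth (20
accepted mutations) and the rest at quarter depth — and each allotype adds
Poisson tip mutations.  This deliberately unbalanced shape puts the
deepest synonymous split past twice the mean, the regime of long-lived
balanced allelic lineages.  A proposed point mutation is accepted with
relative weight 1 if synonymous, w_pbr (default 6) if nonsynonymous at a
PBR codon, and w_nonpbr (default 0.6) elsewhere; stop-creating changes are
rejected except for the single injected pseudogene.  w_pbr = w_nonpbr = 1
is the neutral null.  Every accepted mutation, allele frequency, true
genotype and clone count is written to the truth record, so each stage's
error is computable exactly.

What passing the synthetic tests shows: the estimators recover planted
parameters (PBR elevation, inbreeding F, drift, crossovers) under the
model's assumptions — uniform base-level mutation, independent codons, no
sequencing chimeras, no allele-specific amplification failure beyond the
configurable bias, double peaks perfectly derived from the true genotype.
What it does not show: robustness to real chromatogram noise, null
alleles from primer-site variation, or recombination histories more
complex than a single boundary crossover.

Under the neutral null the estimated d_N/d_S averages slightly below 1
(≈ 0.93 over replicates): minimal-pathway counting undercounts
within-codon multiple hits, a known small-sample property of counting
methods.  The calibration test therefore bounds the replicate mean in a
symmetric band around 1 rather than asserting exact unity.

## Problem sizes in the shipped tests

The default test suite and the acceptance script run desk-scale problems:
panels of 44 variants, bootstrap sizes 1–200 where only determinism or a
point estimate is asserted, 10–100 simulation replicates for calibration
and recovery rates, 96-individual cohorts for genotyping accuracy.  These
sizes give Monte-Carlo errors comfortably inside the asserted tolerances;
production analyses should use the defaults (1 000 bootstrap replicates,
10⁵ HWE shuffles) recorded in the config objects.
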
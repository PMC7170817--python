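# Methods

This note documents the statistical models, conventions and numerical choices
behind `abctrans`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Variants are biallelic records keyed by (chrom, pos, ref, alt) with 1-based,
fully closed coordinates; multi-allelic sites are decomposed into one record
per alternate allele and regrouped on (chrom, pos, ref) where a site-level
view is needed (e.g. the triallelic *ABCB1* position 893). Protein residues
are 1-based inclusive. Allele counts and numbers are carried per population
panel; the eight panels default to the published gnomAD cohort sizes (12,020
AFR, 17,210 AMR, 5,076 ASJ, 9,435 EAS, 15,391 SAS, 12,897 FIN, 63,369 NFE,
3,234 OTH; 138,632 individuals in total).

The *pooled* frequency of a variant is allele-number weighted,
`Σ_p ac_p / Σ_p an_p`, i.e. the whole-cohort frequency. Rarity is defined on
the *folded* pooled frequency `min(af, 1−af)`: MAF < 1% is rare, MAF < 0.1%
very rare, with strict thresholds (exactly 1% is common). Burden, by
contrast, uses the *unfolded* alternate-allele frequency, because it counts
alternate alleles carried: a deleterious variant at 87% contributes
2 × 0.87 = 1.74 expected alleles per diploid genome.

The clinical fixture tables store per-population minor-allele frequencies in
percent exactly as printed in their source, without folding, including
named-allele frequencies above 50%. "N.A." cells are missing and excluded
from min/max/fold-range statistics; cells printed as an upper bound
("< 0.1") are parsed as the bound and flagged as censored.

## Deleteriousness calls

A variant is putatively deleterious when it is

1. a loss-of-function-like class — frameshift, in-frame indel, start-lost,
   stop-gained, canonical splice site — regardless of predictor calls, or
2. a missense variant for which `k/m ≥ 0.5`, where `k` is the number of
   predictors calling it damaging and `m` the number of *available*
   (non-missing) calls among SIFT, PolyPhen2, MutationAssessor, VEST3 and
   Eigen.

The denominator is the available calls, not five, because VEST3/Eigen
coverage is incomplete in practice; a tie (exactly 50%) goes to deleterious.
Missense variants with no available call are *unscored* and excluded from
both the deleterious and the neutral tallies and from burden — there is no
evidence either way. Non-protein-affecting classes (synonymous, UTR, other)
are neutral by class even if predictor scores are present. Numeric predictor
scores are never thresholded here; inputs must be pre-binarized calls. For
genes with a Mendelian inheritance annotation, ClinVar benign/likely-benign
variants are removed before downstream analysis.

The loss-of-function set used for disease-risk aggregation is strictly
{frameshift, start-lost, stop-gained, splice site}; in-frame indels are
deleterious-by-class but not LoF.

## Burden and population specificity

The per-individual burden in population *p* is the expectation
`B_p = Σ_v 2·af_p(v)` over deleterious variants, i.e. the mean count of
deleterious alternate alleles in a diploid genome under Hardy–Weinberg
equilibrium (HWE). Its rare component restricts the sum to variants with
folded pooled MAF < 1%. The closed form is validated by a genotype simulator
that draws per-variant dosages Binomial(2, af) and must agree within three
standard errors at n = 10⁵.

A deleterious variant is *observed* in a panel when its allele count there is
at least 1; it is population-specific when observed in exactly one of the
seven named panels. The heterogeneous OTH panel is excluded from this
partition.

## Recessive disease risk

For an autosomal-recessive gene, the aggregated LoF frequency in population
*p* is `q = min(1, Σ af_p)` over the gene's LoF variants. Under HWE the
affected (biallelic) frequency is `q²` — aggregating across variants before
squaring deliberately counts compound heterozygotes as affected — the carrier
frequency is `2q(1−q)`, and the display form is "1 in round(1/q²)" with no
further rounding. The sum is used rather than `1 − Π(1−q_v)`; the two are
indistinguishable at the frequencies involved. Genes with autosomal-dominant
or X-linked inheritance are refused: the approach requires heterozygous loss
to be phenotypically silent.

## Gene and domain summaries

Length normalization divides the exonic variant count by the coding-sequence
length in kb (only exonic variants are counted, so CDS rather than genomic
length is the denominator). Domain densities assign each protein-affecting
variant with a residue annotation to the unique domain interval containing
it, or to the residual "other" segment; both an all-protein-affecting and a
deleterious-only mode are exposed, and output tables label which is used.
Residues beyond the annotated protein length are skipped. Subfamily
comparisons report the fold difference of mean per-gene counts
(target / all others) plus one-way ANOVA across subfamilies
(`scipy.stats.f_oneway`; an all-identical degenerate input reports F = 0).
Observed/expected constraint ratios carry exact (Garwood) Poisson 90%
intervals, `[χ²(0.05, 2k)/2, χ²(0.95, 2k+2)/2] / expected`; published
constraint scores (o/e, Z, pLI) are consumed as annotations, never computed.

## Linkage disequilibrium

For haplotype frequencies (p_AB, p_Ab, p_aB, p_ab): `D = p_AB − p_A·p_B`,
`r² = D²/(p_A p_a p_B p_b)`, and `D′ = |D|/D_max` with
`D_max = min(p_A p_b, p_a p_B)` for D > 0 and `min(p_A p_B, p_a p_b)` for
D < 0. From unphased dosages, haplotype frequencies are maximum-likelihood
estimates from the standard two-locus EM under HWE (random union of
haplotypes): only double heterozygotes are phase-ambiguous; the E step splits
them between the coupling and repulsion phases in proportion to
`f_AB f_ab : f_Ab f_aB`. The EM starts at linkage equilibrium (products of
observed allele frequencies) and stops when the largest absolute frequency
change falls below 1e-10 or after 1000 iterations, whichever first; the
result records the iteration count, a convergence flag and the log-likelihood
trace, which is non-decreasing by construction. Monomorphic loci yield a
flagged result with undefined r² and D′. r² and D′ are clipped to [0, 1]
against float round-off at the boundaries. `r² ≤ D′` is not asserted
anywhere — it is not a theorem.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
every draw flowing from one integer seed through per-gene sub-streams
(`SeedSequence((seed, stage, gene_index))`), so identical configurations give
byte-identical output tables.

**Gene family.** 48 genes in subfamilies A:12, B:11, C:12, D:4, E:1, F:3,
G:5, with coding lengths uniform on 2,100–6,900 bp (family mean ≈ 4.5 kb)
and the family's typical domain topology: TMD1/NBD1/TMD2/NBD2 backbones,
two large ECDs for A-family genes, an accessory TMD0 for half of the B/C
members. Inheritance modes are drawn per gene (AR 0.35, AD 0.06, XL 0.02,
none 0.57), giving ≈ 17 AR genes at the default scale.

**Site frequency spectrum.** Ancestral frequencies follow a truncated power
law with density ∝ x^(−shape) on [1/277,264, 0.5], sampled by inverse CDF.
The default shape is 2.2 — steeper than the neutral 1/x spectrum, as expected
under population growth — chosen by calibrating the *emitted* cohort to the
rare-dominated composition the analysis assumes: with the default panels
≈ 98% of emitted variants have pooled folded MAF < 1% (the generator's
contract asserts ≥ 95%).

**Population differentiation.** Panel frequencies follow the Balding–Nichols
model: Beta draws with mean p and variance F_ST·p(1−p) (shape parameters
p(1−F)/F and (1−p)(1−F)/F), followed by binomial allele-count sampling at
2N alleles per panel. The default F_ST is 0.05, co-calibrated with the
spectrum shape: it is within the plausible range for this panel set (which
contains several closely related European panels alongside continental ones)
and keeps large-panel Beta excursions from pushing rare ancestral alleles
above 1% pooled frequency. A method-of-moments estimator recovers the input
F_ST from 10⁴ simulated variants within 10%.

**Ascertainment.** Candidate sites are drawn in batches until the gene's
quota (Poisson with mean cds_kb × 290 variants/kb, matching the family-wide
total of ≈ 62,000 emitted variants at default scale) of sites segregating in
the sampled cohort (1 ≤ Σac < Σan) is met. The adaptive batch sizing is
deterministic given the seed.

**Annotations.** Consequence classes are drawn i.i.d. from fixed proportions
(missense 0.531, synonymous 0.231, UTR 0.167, the remainder LoF-like classes
and other). Protein-affecting variants get a latent truth state: LoF-like
classes are truly deleterious; missense variants are deleterious with
probability 0.46 (the deleterious share of missense variation at cohort
scale). Each predictor independently calls deleterious with probability
`sensitivity` on true positives and `1 − specificity` on true negatives
(defaults 0.8/0.8, typical published performance), and is missing at
per-algorithm rates (3–15%, higher for VEST3/Eigen). ClinVar benign labels
are sprinkled on truth-neutral variants of disease genes at rate 0.02. CNV
events are Poisson per gene (mean ≈ 21, ≈ 1,000 family-wide) with
frequencies log-uniform on 10⁻⁶–10⁻³.

**What the generator does not emulate — and what passing tests show.**
Consequence class and deleteriousness are independent of frequency: there is
no purifying-selection coupling, so common deleterious and LoF variants are
far more frequent than in a real selected genome. Absolute burden and
aggregated-LoF levels in simulations are therefore inflated relative to real
cohorts (tens rather than ≈ 10 deleterious alleles per individual), and the
singleton share (≈ 13%) is well below a real cohort's (> 50%): the
Balding–Nichols equilibrium model produces clumpier rare-variant sharing
than the very young, panel-private alleles of real data. Passing tests
therefore demonstrate correctness of the estimators and their mutual
consistency (closed forms vs simulation oracles, truth recovery within
Monte-Carlo error), not that the simulated cohort reproduces any published
cohort's absolute numbers. Cohort-scale published values (total variant
counts in the tens of thousands, per-individual burden ≈ 10, ≈ 76%
population specificity, burden–constraint correlations) require the real
aggregation-database inputs and are out of scope for the synthetic tests.

## Numerical and design choices

- Pooling for rarity uses the allele-number-weighted whole-cohort frequency
  (including OTH); nothing in the interface depends on a per-population
  maximum definition.
- Degenerate inputs: all-zero allele numbers raise an undefined-frequency
  error; zero burden leaves the rare fraction undefined rather than zero;
  empty variant tables yield empty report bundles with a warning and exit
  success.
- `fold_range` over clinical frequencies excludes zero entries (with a
  logged warning) rather than returning infinity; censored upper-bound cells
  participate at their bound.
- Multi-allelic clinical transcriptions are validated by the requirement
  that named-allele frequencies sum to 100 ± 0.3 per population
  (transcription rounding); violations are logged, not fatal.
- Report tables are written with fixed float formatting (`%.8g`) and LF line
  endings so that identical configurations are byte-identical; the manifest
  records the seed, a SHA-256 of the canonical JSON configuration, and the
  package version, and deliberately no timestamps.
- Problem sizes in the validation suite (10⁵ genotypes for burden
  Monte-Carlo, 10⁴ variants for F_ST recovery, 10⁴ individuals for EM
  recovery, 10⁶ diploids for prevalence, a 12-gene cohort for end-to-end
  truth recovery, and an 8-individual two-locus instance for the 10⁻³
  simplex-grid likelihood check) were chosen to make three-standard-error
  bounds decisive at desk scale.

## Command-line interface

`abctrans {simulate, classify, burden, popspec, disease-risk, summarize, ld,
clinical, report}` are thin wrappers over the library. `classify` appends
rarity/protein_affecting/lof/deleterious_call/call_basis columns to the input
table, so its output is directly consumable by `burden`, `popspec` and
`disease-risk`. All subcommands exit non-zero on malformed input, naming the
offending file and line.
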
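# Methods

This note documents the statistical procedures implemented in beanpop,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Genotype representation

All analyses run on an `individuals × loci` matrix of diploid codes
0/1/2/missing (0 = homozygous reference, 2 = homozygous alternate).
Positions are 1-based throughout; no strand handling is attempted
because the DArT sequence tag defines the reported alleles. In the
two-row DArT report, per-locus codes are derived from the
(reference-row, SNP-row) presence pair: (1,0) → 0, (0,1) → 2,
(1,1) → 1, and (0,0) or any no-call → missing. Single-row records
(dominant SilicoDArT markers) are skipped with a logged count; only
codominant SNPs are analyzed.

## Marker indexes

Per-locus indexes are computed over called individuals:
FreqHomRef/FreqHets/FreqHomSnp are genotype-class fractions;
OneRatioRef = FreqHomRef + FreqHets (the fraction of called samples in
which the reference allele row is present), and symmetrically
OneRatioSnp. PIC uses the binary two-state row formula
`1 − [f² + (1−f)²]` applied to each row's OneRatio, matching the DArT
convention of separate PICRef/PICSnp columns; AvgPIC is their mean. A
genotype-based PIC is deliberately not offered — the row convention is
what DArT reports print, and mixing conventions invites silent
inconsistency. Average read depths and reproducibility scores are
passed through from the report; they cannot be recomputed from codes.
A locus with zero called individuals gets NaN metrics, never zero.

SNP density uses fixed, non-overlapping, half-open 200-kbp bins;
"rolling" presentations of density are treated as plotting language,
not computation.

## Filtering

Canonical order: individuals (call rate ≥ 0.8) → loci (call rate
≥ 0.95) → monomorphic removal. Removing low-quality individuals first
preserves more loci, since locus call rates improve once bad
individuals are gone. Call-rate thresholds are inclusive (≥); the MAF
filter used before LD is strictly exclusive (> 0.05), with a 1e-9
epsilon so count-ratio round-off cannot leak a boundary locus through.
A locus with a single heterozygote is polymorphic (both alleles seen).
Every stage returns a removed/retained report and appends to the
dataset's provenance log.

## Exact Hardy–Weinberg test

The Levene–Haldane exact test conditions on the observed allele counts
and enumerates every heterozygote count of matching parity; the
two-sided p-value sums the probabilities of all configurations no more
probable than the observed one (ties included, at relative tolerance
1e-12). Probabilities are computed with log-factorials (`gammaln`), so
the test is stable at sample sizes far beyond small germplasm panels.
Monomorphic samples give p = 1. The standard exact p (not mid-p) is
used. The genome screen tests each locus within each population,
skipping groups with fewer than 2 called genotypes or no variation, and
reports raw p ≤ α by default; a Bonferroni option exists but is off,
since a raw screen is the common reporting practice for such panels.

Distributions are cached by (n, allele count); an exhaustive check that
they sum to 1 for all n ≤ 50, and agreement with brute-force
enumeration of all allele placements at n ≤ 6, are part of the test
suite.

## Diversity and inbreeding

Per population and locus (n = called genotypes at that locus, not the
census): Ho = heterozygotes/n, He = 1 − p² − q²,
uHe = He · 2n/(2n − 1), with population values the unweighted means
over assessed loci and F_IS = 1 − mean(Ho)/mean(uHe). Loci uncallable
in a population are excluded from its means rather than zero-filled.
Note that for a single-individual population uHe = 2·He and F_IS = 0
identically — an artifact of the n = 1 correction factor worth keeping
in mind when census sizes are tiny. Means are over all assessed loci by
default; a `polymorphic_only` flag restricts them to loci polymorphic
anywhere in the dataset, since both conventions appear in the field.

## Allele sharing

For a population pair, over loci called in both: a fixed difference
requires |p₁ − p₂| ≥ 1 − tolerance (default tolerance 0, i.e. strict
fixation for different alleles; the parameter exists because strict
fixation is noisy in small samples). A private allele is an allele with
nonzero frequency in one population and zero in the other, counted per
allele per locus (0–2 per locus per side). AFD is the mean |p₁ − p₂|.
The Chao1 correction `S + f1(f1−1)/(2(f2+1))` is applied to each
population's private-allele copy counts across the shared loci, with
f1/f2 the private alleles seen as exactly one/two copies — an estimate
of private richness the sample missed. This Chao definition is this
package's own; other tools may bin singletons differently, so Chao
columns should be compared only within one toolchain.

## Linkage disequilibrium

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete individuals (composite LD). No phasing or EM
haplotype-frequency estimation is attempted: in a highly selfed panel
heterozygotes are rare (they are retained, as dosage 1, since dropping
them would shrink n unevenly), and composite r² is the robust unphased
default. Pairs with fewer than 4 complete individuals or a constant
dosage vector are skipped and counted.

Significance is a permutation test on one locus's genotype vector with
the add-one estimator p = (1 + #{r²* ≥ r²})/(n_perm + 1). Because
dosages take three values, the permutation statistic has atoms and the
tie-inclusive estimator is *conservative by construction*: the true
P(p ≤ 0.05) sits around 0.035–0.045 rather than 0.05 for panel-sized
samples. This is a validity feature, not a defect — the reported p
never understates significance. The acceptance suite therefore checks
calibration in its exact form: the reported p is never anticonservative,
and the rank of the observed r² among permuted ones with ties broken at
random is exactly uniform.

Per-chromosome summaries report the all-pairs mean r², the fraction of
pairs with p < 0.001, the inter-chromosomal (unlinked) baseline mean,
and a decay curve: a lowess (locally weighted first-degree polynomial,
span 0.3, zero robustness iterations for determinism) fit of r² against
distance, interpolated onto a 100-point grid, with the first grid
distance below r² = 0.2 reported as the decay range. Chromosomes with
fewer than 10 pairs are flagged low-confidence. All within-chromosome
pairs are computed up to a budget (default 2×10⁶), beyond which pairs
are uniformly subsampled with the run seed.

## AMOVA

Each individual contributes two pseudo-haploid allele rows (code 1 →
(0,1)); squared Euclidean distances between allele rows, rescaled by
the number of loci compared when cells are missing, feed the standard
nested sums of squares for among-populations / among-individuals-within
/ within-individuals. Variance components use the nested-ANOVA expected
mean squares with the unequal-size coefficient; percents floor negative
components at zero (raw values are retained). Phi_ST, Phi_IS and Phi_IT
follow. Permutation nulls: whole-individual relabeling across
populations (among-population component), allele-row re-pairing within
populations (among-individual component), and allele-row re-pairing
across the panel (total, tested on Phi_IT); p uses the add-one
estimator. Populations of size 1 are excluded with a warning — a lone
individual carries no within-population information.

## PCA

Missing dosages are mean-imputed per locus, columns centered, and the
matrix decomposed by SVD; explained percents are squared singular
values over their total. Axis signs are made reproducible by forcing
the largest-magnitude loading of each axis positive.

## Synthetic panels

The generator emulates a small selfing-crop germplasm panel:

* **Divergence** — Balding–Nichols: ancestral reference-allele
  frequency p ~ Uniform(maf_floor, 1 − maf_floor), population
  frequencies Beta(p(1−θ)/θ, (1−p)(1−θ)/θ). θ is an F_ST-scale
  parameter.
* **Inbreeding** — genotype mode draws from P(0) = p² + Fpq,
  P(1) = 2pq(1−F), P(2) = q² + Fpq (infeasible negative F clamped and
  logged). Haplotype mode instead gives each population a pool of
  haplotypes built as a Markov chain along each chromosome — adjacent
  loci at distance d keep the same latent ancestry draw with
  probability exp(−d/λ) — and individuals draw two pool haplotypes,
  the same one with probability 2F/(1+F). This reproduces both
  distance-decaying LD and a selfing-like heterozygote deficit without
  simulating generations.
* **Missingness** — i.i.d. masking at a fixed rate. Loci are placed
  uniformly at random on equal-length chromosomes and sorted.

Defaults mirror the target regime: 8 populations of sizes
(10, 10, 10, 8, 5, 3, 3, 1) — 50 individuals, 13,000 loci on 11
chromosomes of 49 Mbp, θ = 0.4 (pairwise AFD in the 0.3–0.46 range),
F = 0.8 (heterozygote fractions of a few percent), 8% missingness,
maf_floor = 0.05. The dataclass default is genotype mode (λ = 0);
`study_config()` switches on haplotype mode with λ = 10 Mbp, giving a
gradual decay with appreciable LD to ~20 Mbp. A single RNG stream,
seeded explicitly, drives each dataset; downstream stochastic stages
(permutations, pair subsampling) take their own seeds.

What the generator does **not** emulate: coalescent genealogies and
mutation processes, centromere-driven marker-density patterns,
admixture between clusters, and locus-specific error or depth
structure. Consequently, passing tests demonstrate estimator
correctness and calibration under a clean, known-truth model — not that
any particular real panel will show the same magnitudes.

## Problem sizes used in the test and acceptance suites

The property-based checks run at sizes chosen to make each property
meaningful while staying quick: F_IS recovery at 2×25 individuals ×
5,000 loci over 10 seeds; HWE type-I calibration at 500 individuals ×
300 common-allele loci × 10 seeds (the exact test is discrete and
conservative at small n, so a ±2-SD band around the nominal level is
only informative where the null distribution is dense); LD calibration
over 2,000 statistically independent locus pairs at n = 25 with 199
permutations; AMOVA detection at θ = 0.3 with 3×10 individuals and
label-permutation calibration over 10 seeds.

## Known limitations

* The exact-test screen reports raw p-values by default; at 10⁴ loci ×
  8 populations a raw α = 0.05 screen is descriptive, not confirmatory.
* Composite r² conflates within- and between-haplotype association
  under inbreeding; it is the appropriate unphased estimator here but
  is not comparable with phased haplotype r² in magnitude.
* Chao-corrected private-allele estimates are definition-sensitive
  (see above).
* AMOVA assumes missingness is ignorable after call-rate filtering;
  the pairwise-complete rescaling is biased if missingness correlates
  with genotype.
* Lowess decay fitting is descriptive; no parametric decay model
  (e.g. expected-r² recombination curves) is fitted.
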
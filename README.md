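# beanpop

Population-genetic characterization of DArTseq SNP panels in selfing
crops, built for small germplasm collections — landraces and heirloom
varieties genotyped at ~10⁴ biallelic markers across a handful of
varietal clusters. The package targets the standard analysis battery a
plant-genetic-resources lab runs on such a panel: marker quality
indexes, call-rate trimming, exact Hardy–Weinberg testing, diversity
and inbreeding summaries, pairwise private/fixed-allele accounting,
linkage-disequilibrium structure and decay, AMOVA and PCA — together
with a synthetic-panel generator so every stage is testable without
access to any particular field dataset.

## The data model

Everything operates on an `SNPDataset`: an `individuals × loci` matrix
of diploid genotype codes (0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, missing), with per-individual population
labels and per-locus map positions. Datasets are read from DArT
"two-row" SNP reports (one reference-allele row and one SNP-allele row
of presence scores per locus; single-row SilicoDArT records are skipped
and counted) and exported to VCF 4.2, relaxed PHYLIP and STRUCTURE
formats.

## The statistics at the core

* **Exact Hardy–Weinberg test** (Levene–Haldane). Conditional on the
  allele counts (n_A, 2n − n_A), the heterozygote count h has
  probability

      P(h) = 2^h n! / (n₁! h! n₂!) · n_A! (2n − n_A)! / (2n)!

  with n₁ = (n_A − h)/2, n₂ = (2n − n_A − h)/2; the two-sided p-value
  sums P(h′) over configurations no more probable than the observed one.
* **Diversity / inbreeding.** Per population, per locus: Ho = hets/n,
  He = 1 − p² − q², uHe = He·2n/(2n − 1), and
  F_IS = 1 − mean(Ho)/mean(uHe) over loci.
* **Allele sharing.** Per population pair, over loci called in both:
  fixed differences (|p₁ − p₂| = 1), private alleles (present in one
  population, absent in the other), mean allele-frequency difference
  (AFD), and a Chao1 singleton/doubleton correction of the private
  counts.
* **LD.** Composite r² (squared Pearson correlation of 0/1/2 dosages,
  no phasing needed), permutation p-values, and per-chromosome decay
  curves fit by locally weighted regression with the distance at which
  the fit first crosses r² = 0.2.
* **AMOVA.** Three-level variance partition (among populations, among
  individuals within populations, within individuals) from squared
  Euclidean allelic distances, with Phi statistics and permutation
  significance; **PCA** on mean-imputed centered dosages.

## Worked example

```python
from beanpop import (SimulationConfig, simulate_dataset, filter_individuals,
                     filter_loci, remove_monomorphic, diversity_report,
                     hwe_screen, pair_sharing, hwe_exact)

cfg = SimulationConfig(n_pops=3, n_ind=(10, 10, 5), n_loci=2000,
                       theta=0.4, inbreeding=0.8, missing_rate=0.08, seed=7)
ds = simulate_dataset(cfg)
ds, _ = filter_individuals(ds, 0.8)   # genotype call rate ≥ 0.8
ds, _ = filter_loci(ds, 0.95)         # locus call rate ≥ 0.95
ds, _ = remove_monomorphic(ds)        # 740 loci retained
print(diversity_report(ds).round(3))
```

prints

```
            poly_loc  mono_loc     ho     he    uhe    fis
population
pop1             483       257  0.051  0.217  0.229  0.779
pop2             502       238  0.051  0.225  0.237  0.784
pop3             388       352  0.055  0.199  0.222  0.750
```

— strong heterozygote deficits (F_IS ≈ 0.75–0.78) recovering the
simulated selfing level F = 0.8. The exact-HWE screen flags the same
kind of configurations a real selfing panel shows, e.g. a locus with
genotype counts (5, 0, 5) in 10 individuals:

```python
>>> hwe_screen(ds, alpha=0.05)[0].p_value
0.00136...
>>> round(hwe_exact(2, 0, 6), 5)     # 2 hom-ref, 0 het, 6 hom-alt
0.01538
>>> pair_sharing(ds, "pop1", "pop2").totalpriv
367
```

The same workflow is available from the shell:

```sh
beanpop simulate --config sim.yaml --out-prefix panel
beanpop diversity --in panel.csv --popmap panel.popmap.tsv --out div.tsv
beanpop run --config run.yaml        # full pipeline with manifest
```

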
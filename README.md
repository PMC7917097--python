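# founderhap

Tracing founder haplotypes through pedigreed crop populations, and using
them as multi-allelic markers for genomic prediction and GWAS.

Clonally propagated fruit-tree breeding programs often descend from a
handful of founder cultivars. Every chromosome in such a population is a
mosaic of the founders' chromosomes, so with `F` diploid founders the
whole population can be described by `2F` ancestral haplotypes — 14 for a
typical seven-founder apple program. `founderhap` reconstructs that mosaic
from biallelic SNP data and a pedigree, then exploits it:

1. **Phase** (`founderhap.phase`) — pedigree-aware phasing of SNP
   genotypes with sporadic-missing imputation (trio logic, progeny-backed
   parent phasing, a windowed linkage heuristic), plus a phasing-accuracy
   metric.
2. **Trace** (`founderhap.trace`) — for each individual, each phase slot
   is assigned to a parent by correlation; the slot is explained as a
   mosaic of that parent's two phases by a minimum-penalty Viterbi path
   (allele mismatch = 1, crossover = 10); founder labels `2f-1 / 2f`
   propagate down the pedigree in topological order. Regions that cannot
   be traced keep the raw biallelic codes `2F+1 / 2F+2` (15/16 for seven
   founders).
3. **Predict** (`founderhap.predict`) — EM-BayesB whole-genome regression
   (spike-and-slab prior, `gamma = 0.01`, `v = 1`, `S = 0.01`) on SNP
   dosages or founder-haplotype counts, with leave-one-family-out
   cross-validation pooled over all full-sib families.
4. **Associate** (`founderhap.associate`) — MCMC-BayesB GWAS
   (`pi = 0.002`, 50,000 cycles / 20,000 burn-in) with a VanRaden-GRM
   polygenic random effect against genetic stratification; significance by
   the 99th percentile of the permutation (n = 100) distribution of the
   per-marker posterior inclusion frequency ("gamma").
5. **Transmit** (`founderhap.transmit`) — a gene-dropping test (10,000
   replicates) of whether a focal founder haplotype was transmitted more
   or less often than Mendelian chance, against the initial expectation
   `1/2F` (0.07 for seven founders).

A forward simulator (`founderhap.simulate`) generates pedigreed diploid
genomes with known founder-origin truth (Haldane meiosis, array-like
genotyping error, missingness) and haplotype-architecture phenotypes with
year effects, so the whole pipeline is testable without proprietary data.
`founderhap.pheno` turns multi-year trait records into genotype BLUPs
(year fixed, genotype random) that serve as working phenotypes.

## Worked example

Simulate a three-generation population (7 founders, 3 chromosomes at
array-like marker density, 0.2% genotyping error, 0.5% missingness),
phase it, trace the 14 founder haplotypes, and test one haplotype for
non-random transmission:

```python
from founderhap import (SimConfig, simulate_population, mendelian_phase,
                        phasing_accuracy, trace_founder_haplotypes,
                        coverage_stat, haplotyping_accuracy)
from founderhap.simulate import three_generation_design
from founderhap.transmit import transmission_test

cfg = SimConfig(chromosomes=[(690, 70.0)] * 3,
                pedigree=three_generation_design(),
                genotype_error_rate=0.002, missing_rate=0.005, seed=7)
truth, _ = simulate_population(cfg)

phased = mendelian_phase(truth.observed, truth.pedigree)
print(f"phasing accuracy:      {phasing_accuracy(phased.phased, truth.phased):.3f}")

result = trace_founder_haplotypes(truth.pedigree, phased.phased)
print(f"coverage:              {coverage_stat(result.assignment, result.assignment.individuals):.3f}")
print(f"haplotyping accuracy:  {haplotyping_accuracy(result.assignment, truth.assignment):.3f}")

test = transmission_test(truth.pedigree, result.assignment, "S1_100",
                         focal_label=3, n_reps=10_000, seed=7)
print(f"observed frequency:    {test.observed_freq:.3f}")
print(f"initial expectation:   {test.initial_expected_freq:.3f}")
print(f"p(increase):           {test.p_increase:.3f}")
```

Output:

```
phasing accuracy:      0.967
coverage:              1.000
haplotyping accuracy:  0.931
observed frequency:    0.084
initial expectation:   0.071
p(increase):           0.392
```

96.7% of alleles are phased correctly; every allele in the population
receives a founder label (coverage 1.0), and 93.1% of those labels match
the simulator's truth. Haplotype 3 is carried at frequency 0.084 against
the Mendelian expectation of 1/14 ≈ 0.071, an excess that gene dropping
shows is well within chance (p = 0.39).

A command-line interface mirrors the library
(`founderhap simulate | phase | trace | gp | gwas | transmit | ld`); run
`founderhap --help` for options.

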
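# Methods

This note documents the models and algorithms implemented in
`founderhap`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the package's known limitations.

## The tracing model

A population descended from `F` diploid founders carries at most `2F`
ancestral chromosome types. Founder `f` (1-based, in pedigree founder
order) owns haplotype labels `2f-1` and `2f`; alleles whose ancestry
cannot be established keep raw biallelic codes `2F+1` (allele 0) and
`2F+2` (allele 1) — the familiar 15/16 when `F = 7`. Tracing proceeds in
four steps per individual, parents before children:

1. **Phasing.** `mendelian_phase` resolves dosages into two phase slots
   (slot 0 maternal, slot 1 paternal wherever trio logic decides):
   (a) a heterozygous site is phased when either parent is homozygous,
   iterated with forced imputation to a fixpoint; Mendelian-impossible
   child sites are set missing and counted; (b) a *progeny-backed* pass
   phases parents — founders in particular, who have no parents of their
   own — from the alleles they demonstrably transmitted (offspring
   homozygous, or offspring heterozygous with the other parent
   homozygous), using a greedy left-to-right orientation scan that tracks
   which parental slot each offspring currently carries and treats a
   persistent disagreement as an offspring recombination; (c) leftover
   heterozygous sites take the orientation agreeing with the more
   frequent two-locus haplotype (over the already-phased population) with
   the nearest phased heterozygous site within `window` markers (default
   50); ties put allele 0 in slot 0. Remaining missing genotypes become
   the marker's major-allele homozygote; an imputed mask is reported.
   An external LD-model phaser can be substituted freely: the tracer
   accepts any phased VCF.
2. **Parental-phase assignment.** Per chromosome, each child phase slot
   (a 0/1 vector) is correlated with each parent's dosage vector
   (0/1/2); the slot→parent pairing maximizing the summed correlation is
   taken. When a correlation is undefined because a vector is constant
   (a fully homozygous parent), the score degenerates continuously to
   mean allele agreement mapped onto [-1, 1]. Chromosomes with fewer
   than `correlation_min_informative` (default 10) jointly observed
   markers, or exactly tied pairings (e.g. genotypically identical
   parents), stay unassigned and keep raw codes.
3. **Haplotype blocks.** The assigned slot is explained as a mosaic of
   the parent's two phases by a minimum-penalty path over states
   {phase 1, phase 2}: each allele mismatch costs `mismatch_penalty`
   (default 1), each state switch `crossover_penalty` (default 10);
   missing alleles cost nothing, and markers where the parent's phases
   agree never influence switching. The dynamic program is exact; ties
   prefer no state change, then phase 1 — determinism was the goal, and
   fewer recombinations is the biologically conservative choice. Both
   states start at zero penalty (no prior on which phase leads a
   chromosome).
4. **Label propagation.** The child's label at a marker is the parent's
   label on the phase the path selects there. Unassigned sides, unknown
   parents, and positions where the parent itself is untraced fall back
   to the raw code of the child's own allele.

### Properties and honest limits of the penalty method

The 1:10 penalty ratio has a sharp operational meaning: a true segment is
recovered only when it spans more than ~10 *informative* markers
(parent heterozygous). Two consequences, both verified empirically by the
test suite:

* **Crossover-placement ambiguity.** A crossover falling inside a run of
  markers where the parent's phases agree is unobservable; the path puts
  the switch at one end of the run while the physical crossover sits
  inside, so a few markers per crossover carry the sibling label with an
  identical allele. This affects 1–2% of entries under any allele
  frequency spectrum (the ambiguous-marker probability `p² + (1-p)²` is
  at least 1/2), so exact label agreement with a forward-simulated truth
  plateaus near 0.98–0.99 even with error-free data and true phases.
* **Density dependence.** At array-like density (~690 markers per
  chromosome) short segments are almost always detected and
  perfect-information accuracy reaches 0.994. Thinned to one tenth of
  that density the same algorithm drops to ~0.87 because whole short and
  terminal segments become cheaper to absorb as mismatches. Accuracy
  claims for this method are therefore claims about a marker density.

Label→allele consistency is exact except where the chosen path paid an
emission mismatch; the test suite asserts this correspondence exactly
rather than pretending the mismatches do not exist.

### Accuracy metrics

`phasing_accuracy` aligns the estimated phase pair to the reference per
individual and chromosome by whichever global slot orientation matches
more alleles, then counts matched / compared (both non-missing) alleles.
Switch errors inside a chromosome therefore penalize accuracy.

`haplotyping_accuracy` compares founder labels wherever the reference
carries one, after maximizing agreement over (a) the label pair within
each founder, per chromosome — a founder's two haplotypes have no
canonical order, so any two assignments fix them arbitrarily and an
unaligned comparison would sit near 50% by construction; the `2^F`
swaps are searched exhaustively (`F ≤ 12` enforced) — and (b) each
individual's slot orientation, nested inside. With `F = 7` founders and
uniformly random labels the metric sits at 1/14 plus a small
maximization bias, as the tests check analytically.

`coverage_stat` is the fraction of (individual, marker, slot) entries
carrying a founder label — the "fraction of SNP information representable
by the founder haplotypes".

## Synthetic data

The simulator is the package's study system, not a fixture: founder
haplotypes are drawn site-wise with per-marker allele-1 frequencies
uniform on `allele_freq_range` (default (0.1, 0.9)); meiosis is Haldane —
crossover count Poisson(length_cM/100), positions uniform in map
distance, no interference; genotyping error is a symmetric per-allele
flip (default 0); missingness masks dosages i.i.d. (default 0). Map
positions are evenly spaced in cM and converted to bp at 2.5 cM/Mb.
Unknown parents contribute novel external haplotypes labeled untraceable.

Three pedigree builders mirror a fruit-tree program: a three-generation
design (7 founders → 42 F1s in 7 crosses → 40 F2s; every founder has
≥ 12 children, which the progeny-backed phaser needs), a breeding design
adding 16 full-sib families of 25 crossed among 17 derived parents
(n = 400 breeding individuals), and an apple-like design reproducing the
published cohort sizes exactly: 185 parental individuals (7 founders plus
two derived generations) plus 659 F1s in 16 families from 17 parents —
844 in total. The default marker grid is 17 chromosomes × 70 markers
(1,190; one tenth of an 11,786-SNP array) at 80 cM per chromosome;
tracing-accuracy studies use 690 markers per chromosome, the array-like
density, per the density analysis above.

Phenotypes: each trait is a list of QTL with per-founder-haplotype effect
vectors — additive QTL add the two carried labels' effects, dominant QTL
take the maximum — plus i.i.d. year shifts and Gaussian noise scaled so
the single-record heritability hits the target. What the simulator does
*not* emulate: ascertainment bias of array SNPs, crossover interference,
mutation, selection during the pedigree, genotype-calling artifacts
correlated along the chromosome, and shared-environment effects beyond
the year. Passing tests therefore certify algorithmic correctness and
behavior under idealized array-like noise, not performance on any real
orchard.

## Year adjustment

Multi-year records are adjusted with `value ~ year (fixed) + genotype
(random intercept) + residual`, fit by REML (statsmodels `MixedLM`,
trying lbfgs, bfgs, then powell); the genotype BLUP is the working
phenotype. Single-year traits degenerate to shrunken centered means with
a warning (the variance split is unidentifiable). Year as fixed is this
package's call — the original mixed-model description names only "the
effect of the year". Ordinal scores are treated as numeric. Note that
with a true genotype variance of zero the REML estimate sits near the
boundary with O(n^-1/2) sampling noise, so BLUPs shrink strongly but are
not numerically zero.

## EM-BayesB (genomic prediction)

Model: `y = mu + sum_j x_j gamma_j b_j + e`, `gamma_j ~ Bernoulli(gamma)`,
`b_j | sigma_j² ~ N(0, sigma_j²)`, `sigma_j² ~ scaled-inv-chi²(v, S)`;
defaults `gamma = 0.01`, `v = 1`, `S = 0.01`, with MAF filters of 0.01
(SNP dosage columns) and 0.0001 (haplotype count columns), both strict
`<`. Missing dosages are column-mean imputed.

The fit is mean-field coordinate ascent with one deliberate subtlety: at
`v = 1` the slab marginal is near-Cauchy, and a point estimate of
`sigma_j²` loses the tail — the exact weighted variational update
collapses every slab to the prior mode and the model learns nothing,
while a plug-in likelihood-ratio variant overfits. The implementation
therefore integrates the effect variance out of the E-step with 16
equal-probability quadrature nodes of its prior; each column's inclusion
probability and conditional effect are mixture averages over the nodes.
Initialization is deterministic (effects 0, residual variance var(y)),
so cross-validation results are reproducible bit for bit. The reported
objective is the residual log-likelihood term; it rises essentially
monotonically (observed dips ≤ ~3% of the total rise, from the
indicator re-weighting). Prediction weights effects by their inclusion
probabilities: `yhat = mu + X (E[gamma] * E[b])`.

Cross-validation leaves one full-sib family out at a time, pools the
held-out predictions over all families, and reports Pearson r with the
observed values; negative r is reported as 0, and a two-sided
no-correlation test p-value accompanies any positive r. Because a single
simulated population leaves the pooled r with a sampling sd of ~0.08,
accuracy claims in the test suite are averaged over replicate
populations, and the haplotype-vs-SNP comparison runs 30 replicates — at
10, a 2:1 true win ratio is indistinguishable from a coin toss.

## MCMC-BayesB (GWAS)

Model: `y = mu + X beta + u + e` with indicators `delta_j ~
Bernoulli(pi)`, `sigma_j² ~ scaled-inv-chi²(v_beta, S_beta2)`, residual
variance `~ scaled-inv-chi²(v_e, S_e2)` (the default `v_e = -2`,
`S_e2 = 0` is the flat improper prior), and a polygenic effect `u ~
N(0, G sigma_u²)` with `G` the VanRaden method-1 GRM computed from SNP
dosages (also for haplotype runs). Defaults: `v_beta = 4`,
`S_beta2 = 0.004`, `pi = 0.002` (≈ 20 expected nonzero markers at
p ≈ 10,000; a consistency warning fires when `pi·p` strays far from
that), 50,000 cycles / 20,000 burn-in, seeded.

Sampling is partially collapsed Gibbs per marker — effect variance from
its conditional (prior when excluded), indicator with the effect
marginalized out, then the effect — which avoids the poor mixing of
naive indicator Gibbs. The polygenic vector is sampled in the eigenbasis
of `G`, where its conditionals are independent normals; non-PSD `G` has
eigenvalues clipped at zero with a warning; `sigma_u²` gets a flat
prior. The association statistic ("gamma") is the per-marker posterior
inclusion frequency over post-burn-in cycles. Significance thresholds
permute `y` (`n_perm = 100` by default), refit, pool every marker's
gamma, and take the 99th percentile; pooling across markers and
permutations (rather than per-permutation maxima) is this package's
declared reading. Rows of `G` are not permuted — the polygenic term
stays attached to the genotypes, so the null preserves the relatedness
structure under a shuffled phenotype. A locus's variance contribution is
`var(X_locus · effects) / var(y)`, clipped to [0, 1].

A desk-scale profile (`GWASConfig.scaled_down()`: 5,000 / 2,000 cycles,
20 permutations) exists for the test suite and scripted studies; library
defaults are unchanged. Sampler correctness is pinned by a conjugate
special case: with `pi = 1`, no polygenic term, and large-df priors the
posterior mean effects must match the closed-form ridge solution, which
the suite checks to Monte-Carlo tolerance.

## Transmission test

At a focal locus, each gene-dropping replicate redraws every meiosis in
the pedigree fairly (each child takes one of each available parent's two
current labels with probability 1/2; unknown parents contribute an
untraceable code), and records the focal label's frequency among the
evaluation subset's `2N` allele slots — untraced slots count in the
denominator, and the subset defaults to all pedigree individuals since
the pedigree carries no population split. One-sided p-values use the
`+1/(n+1)` finite-sample correction against `n_reps = 10,000`
replicates; both directions are reported separately, and the initial
expectation `1/2F` accompanies them. The Monte Carlo process is verified
against exhaustive enumeration of all transmission outcomes on small
pedigrees, and its null p-values are checked for super-uniformity.

## Numerical and policy choices

* Coordinates are 1-based bp, VCF convention; marker order is position
  within chromosome, ties broken by id; REF → 0, ALT → 1.
* Topological order is generation depth (founders first), input-position
  tiebreak; cycles and absent parents are hard errors.
* All stochastic components take explicit seeds; EM and the phaser are
  deterministic by construction.
* Unknown parents are encoded as empty string or "0"; every genotyped
  individual must appear in the pedigree (possibly parentless).
* LD summaries: r² of mean-imputed dosage vectors; decay by
  Nadaraya-Watson regression (Gaussian kernel, default bandwidth 250 kb,
  grid 0–5 Mb); the unlinked threshold is the 95th percentile of r² over
  100,000 random inter-chromosome pairs; a single-chromosome map flags
  the threshold unavailable.

## Known limitations

* The tracer is pedigree-bound: it cannot detect identity by descent
  between individuals whose connecting ancestors are ungenotyped or
  absent from the pedigree.
* Block calls are point estimates (minimum penalty), not posteriors;
  near-tied paths carry no uncertainty flag beyond the penalty itself.
* The built-in phaser has no population LD model; with few genotyped
  relatives its window heuristic degrades toward arbitrary orientation.
* Haplotype-design matrices treat each (marker, label) pair as an
  independent column; the per-marker sum-to-two constraint makes one
  column per marker redundant with the intercept, which shrinkage
  absorbs but an unregularized refit would not.
* EM-BayesB remains a mode-seeking approximation; on traits with many
  borderline signals its cross-validated accuracy trails a full MCMC fit
  and sits slightly below a tuned ridge baseline in our replicates.
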
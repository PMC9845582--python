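# Methods

This note records the statistical model behind each module, the conventions
adopted where several are in circulation, and what the synthetic-data
generator does and does not emulate.

## Genotype model and data handling

A DIP locus is biallelic (deletion D, insertion I); calls are stored as
deletion dosage (II=0, DI=1, DD=2) with an explicit missing state. All
statistics are complete-case per locus: missing calls are excluded from that
locus's counts and, in multi-locus LRs, the locus is skipped for that pair
and the skip counted. A locus with no non-missing call in a population is
reported as absent, never as frequency zero. The sex-determination locus of
mixed panels (e.g. Amelogenin) is treated as metadata and excluded from
autosomal statistics.

## Per-locus forensic parameters

- **He** uses the unbiased small-sample correction 2pq·2n/(2n−1). This is
  the STRAF-style convention and is the variant consistent with published
  parameter tables for panels of this type (e.g. He = 0.2763 at p = 0.8349,
  n = 209).
- **PM** is the sum of squared *observed* genotype proportions (PD = 1 − PM
  exactly); an HWE-expected variant is exposed as
  `match_probability_expected` but is not the default, matching common
  forensic-software behaviour.
- **PE** = Ho²(1 − 2Ho(1−Ho)²) and **TPI** = 1/(2(1−Ho)) are functions of
  observed heterozygosity; both conventions were checked against two
  independent printed (Ho, PE/TPI) pairs before adoption.
- **Rounding** for report display is half-up at 4 decimals
  (`round_half_up`); internal computation is double precision throughout.

## Hardy–Weinberg exact test

The test conditions on the observed allele counts and enumerates every
feasible heterozygote count of matching parity; the p-value sums the
conditional probabilities not exceeding the observed configuration's
(two-sided by probability ordering). Enumeration is exact and deterministic
at forensic sample sizes, so no Markov-chain approximation is used.
Probabilities are computed through log-gamma with a 1e−12 relative slack
when comparing against the observed probability so that analytic ties are
not split by floating-point noise. Monomorphic loci return p = 1 by
convention.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotypes by EM
(only the double heterozygote is phase-ambiguous; convergence tolerance
1e−10 on the frequency vector, 1000 iterations maximum, flagged if not
converged). The test statistic is the likelihood ratio
Λ = 2(lnL_full − lnL_independent); its null distribution is calibrated by
permuting one locus's genotype column, p = (#{Λ_perm ≥ Λ} + 1)/(B + 1) with
B = 10,000 by default and a seeded generator. For tiny n an exhaustive
enumeration over all n! permutations is available. Bonferroni thresholds
follow the panel-testing arithmetic: α/m for m single-locus tests and
2α/(m(m−1)) for the m(m−1)/2 locus pairs.

## Panel combination

CPM, TDP and CPE multiply per-locus terms in log space (log10 for CPM,
log1p/expm1 for the complements), so 43-locus products at the 1e−18 scale
lose no precision; CPM is additionally reported as a mantissa–exponent
string. Loci are assumed independent, which the LD module is there to
verify.

## Kinship likelihood ratios

The pair likelihood under IBD coefficients (k0, k1, k2) factorises through
the one-shared-allele transition kernel T (the shared allele is a uniform
pick from the first individual's two alleles, the other allele a fresh
population draw). Per-locus LRs multiply over unlinked loci and are
accumulated in log10. Two exact identities are used as test oracles: the
nine-cell joint distribution sums to 1 for any hypothesis, and
E[LR | H2] = 1 per locus. The full-sibling joint distribution is also
cross-checked against an independent gene-dropping enumeration over parental
genotypes.

A call at LR limit t is strict (LR > t); ties count as negative. The
(½, ½, 0) hypothesis is labelled half-sibling but is the avuncular/
grandparent equivalence class. No co-ancestry (theta) correction is applied;
frequencies are treated as known.

**Study design.** The discrimination study simulates 1000 pairs per class at
43 loci with frequencies drawn from a truncated normal with mean 0.4993,
SD 0.0954, bounds [0.3080, 0.6480] — the published spectrum of the panel's
East-Asian reference group — and reports accuracy/false-positive rates at
LR limits 1, 10, 100, 1000, 10000. The acceptance script averages ten seeded
replicates of this design; the unit suite additionally checks the simulated
accuracy against an exact convolution of the per-locus log-LR distribution.

## Synthetic data

- **Spectra** are truncated normals because the emulated quantity is
  reported as mean/SD/range only; a Beta alternative would also fit and the
  choice is confined to `sample_frequency_spectrum`.
- **Populations** are HWE per locus; **structure** follows Balding–Nichols
  (subpopulation frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)); the pipeline's
  demo uses F = 0.15 per population, a typical continental-scale divergence.
- **Related pairs** are generated by direct IBD-state sampling rather than
  explicit parental gene-dropping; for unlinked autosomal loci the two are
  distributionally identical (verified by enumeration in the tests) and the
  IBD route is simpler to audit.
- Not emulated: genotyping error, null alleles, mutation, linkage, and
  within-population substructure/co-ancestry. Passing tests therefore show
  correctness of the statistical machinery under the stated model, not
  robustness of a real panel to those artefacts.

## Population-genetic analyses

- **F_ST** is Weir–Cockerham θ with per-locus variance components summed
  across loci before the ratio; negative estimates are retained in the
  matrix, and a zero-clamped copy feeds distance-based methods (NJ, MDS).
- **Nei's distance** is the standard Ds with gene identities pooled over
  loci before the log ratio (gendist convention).
- **Iₙ** uses natural log by default with a configurable base (the measure
  is base-dependent only through a constant); values below 1e−12 snap to 0
  so the zero-iff-identical-frequencies property holds exactly.
- **NJ** uses the standard Q-criterion with deterministic label-order
  tie-breaking; a negative limb length is set to zero and transferred to its
  sister branch (pair-sum preserving), with the number of adjustments
  recorded on the result.
- **MDS** is Torgerson double-centering with eigendecomposition; variance
  fractions are relative to the positive eigenvalues. **PCA** centers
  columns without scaling (dosages at individual level, frequencies at
  population level; missing dosages mean-imputed); signs follow a
  largest-loading-positive convention for reproducibility.

## Ancestry evaluation

Stratified 75/25 split per class, seeded. The reference classifier estimates
per-class deletion frequencies with a pseudocount of 0.5 per allele and
scores individuals by summed log HWE genotype likelihood with a uniform
class prior; ties break by label order, and an all-missing individual is a
no-call. The evaluation protocol (split → fit → predict → confusion matrix
with exact Clopper–Pearson 95% CI on accuracy) is classifier-agnostic: any
scikit-learn-compatible estimator can be passed in. Clopper–Pearson was
chosen because it is the interval that reproduces published accuracy CIs
from their confusion-matrix counts.

With three balanced classes and no between-class divergence the classifier's
accuracy falls to the class prior; accuracy rises monotonically with
between-class F_ST (checked at F ∈ {0.01, 0.05, 0.15}).

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed or Generator, and
the pipeline derives per-stage seeds from one base seed so stages are
isolated and runs are bit-reproducible. Test problem sizes (e.g. 4000-pair
log-LR simulations checked against the exact 43-locus convolution,
60-replicate LD null calibration at B = 99,
500-individual F_ST calibrations) were chosen as the smallest sizes at which
the sampling error of the checked quantity is well below its assertion
tolerance.

## Known limitations

- Parent–child/trio paternity LRs are not implemented (PE/TPI cover the
  parameter side); no linked-marker kinship.
- The LD permutation test recomputes EM per permutation; with B = 10,000
  over all 903 pairs of a 43-locus panel this is minutes of CPU, so
  panel-wide scans should lower B or parallelise externally.
- VCF import is a best-effort convenience for biallelic indels; records are
  classified by REF/ALT length only.
- Multi-allelic (STR) markers, genotyping-error models and theta-corrected
  match probabilities are out of scope.
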
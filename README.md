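# dippanel

Forensic evaluation of biallelic deletion/insertion polymorphism (DIP) marker
panels, written for forensic geneticists validating an identification panel:
per-locus and combined forensic statistics, Monte-Carlo kinship
likelihood-ratio studies, population-differentiation analyses and
biogeographic-ancestry assignment — all runnable end to end on synthetic
genotypes generated to match a panel's allele-frequency spectrum.

## What it computes

A DIP locus is biallelic: a deletion allele D at frequency *p* and an
insertion allele I at *q* = 1 − *p*. For each locus the package reports the
standard forensic parameters

- observed heterozygosity Ho and unbiased expected heterozygosity
  He = 2*pq* · 2*n*/(2*n* − 1),
- polymorphism information content PIC = 1 − (*p*² + *q*²) − 2*p*²*q*²
  (at most 0.375 for a biallelic locus),
- matching probability PM = Σ genotype-frequency² and power of
  discrimination PD = 1 − PM,
- power of exclusion PE = Ho²(1 − 2Ho(1 − Ho)²) and typical paternity index
  TPI = 1/(2(1 − Ho)),
- an exact conditional Hardy–Weinberg test and EM-plus-permutation pairwise
  linkage-disequilibrium tests, with Bonferroni correction,

and combines them across the panel as CPM = Π PM, TDP = 1 − Π(1 − PD),
CPE = 1 − Π(1 − PE), accumulated in log space (a 43-locus panel reaches
CPM ≈ 10⁻¹⁸).

For kinship testing, the likelihood of a genotype pair under a relationship
with IBD coefficients (k₀, k₁, k₂) — full siblings (¼, ½, ¼), half siblings
(½, ½, 0), unrelated (1, 0, 0) — is

P(g₁, g₂ | k) = P(g₁)[k₀P(g₂) + k₁T(g₂|g₁) + k₂𝟙(g₁ = g₂)],

multiplied over unlinked loci; the Monte-Carlo study simulates pairs under
each hypothesis and tabulates accuracy and false-positive rates at LR limits
1–10⁴. Population analyses cover Weir–Cockerham F_ST, Nei's standard genetic
distance, Rosenberg's informativeness for assignment Iₙ, neighbor-joining
trees, classical MDS and PCA; ancestry assignment is evaluated with a
stratified 75/25 split, a frequency-likelihood classifier (a scikit-learn
estimator, swappable for external learners) and a confusion matrix with an
exact Clopper–Pearson 95% CI.

## Worked example

Simulate a 43-locus panel whose deletion-frequency spectrum matches a real
East-Asian reference group (mean 0.4993, SD 0.0954, range 0.3080–0.6480) and
run the full-sibling discrimination study with 1000 pairs per class:

```python
from dippanel import synth, kinship

spec = synth.FrequencySpectrumSpec(seed=1)          # 43 loci, default spectrum
p = synth.sample_frequency_spectrum(spec).table["p_del"].to_numpy()
res = kinship.run_lr_study(p, kinship.FULL_SIBLING, n_pairs=1000, seed=1)
print(res.as_frame().to_string(index=False))
```

```
 lr_limit  accuracy_pct  false_positive_pct
      1.0          96.4                 3.1
     10.0          86.4                 0.4
    100.0          68.5                 0.1
   1000.0          41.5                 0.0
  10000.0          15.9                 0.0
```

At an LR limit of 1, 96.4% of true full-sibling pairs are identified while
3.1% of unrelated pairs are falsely called — the panel separates full
siblings well, but raising the limit to 10⁴ (near-certain calls) identifies
only ~16% of sib pairs. The same study with `kinship.HALF_SIBLING` shows the
panel can only partially resolve half siblings (~80% at LR > 1 with a ~20%
false-positive rate).

The `dippanel` CLI exposes each stage (`synth`, `locus-stats`, `panel-stats`,
`kinship-study`, `fst`, `nei`, `infocalc`, `nj`, `mds`, `pca`,
`ancestry-eval`) plus `run` for a config-driven end-to-end pipeline writing
one report bundle.

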
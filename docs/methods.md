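# Methods

## Problem setting

A closed breeding stock (the "target" population) must be distinguished
from the surrounding commercial gene pool using a small SNP panel typed on
a microfluidic genotyping platform, and re-surveyed over time so that
allele-frequency shifts — e.g. introgression from the commercial pool —
are detected early. gsikit implements the full desk-side analysis: panel
design from pooled sequencing, panel reduction, genotype QC, membership
classification with probability estimates, and epoch-to-epoch divergence
monitoring, together with a simulator that generates data with exactly the
statistical structure the pipeline assumes.

## Synthetic data model

Population structure follows the Balding–Nichols model: each SNP has an
ancestral frequency `p` drawn uniformly from a minor-allele range (default
0.05–0.5, randomly oriented), and each population draws its frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, whose variance `F·p(1−p)` makes the
expected fixation index equal `F`. `F = 0` is the documented degenerate
limit (all populations get `p` exactly). Defaults mirror the study scale
the package targets: 81 markers, two stocks at `F = 0.115`, 100 diploid
individuals per stock, pool depth 100×.

On top of the frequency layer:

* **Pools** — per SNP × pool, depth ~ Poisson(mean depth) (fixed-depth
  optional, so depth heterogeneity can be switched off in tests), alternate
  reads ~ Binomial(depth, freq). Zero-depth cells are legal and logged.
* **Individuals** — dosage ~ Binomial(2, freq): Hardy–Weinberg equilibrium,
  no linkage disequilibrium between markers.
* **Introgression** — frequency-level admixture
  `(1−α)·target + α·source`. This reproduces the population-mean shift and
  the resulting drop in divergence and membership probability; it does not
  model individual admixture pedigrees, so per-individual ancestry variance
  is smaller than in a real introgressed generation.
* **Assay degradation** — uniform missingness at a set rate, appended
  constant-dosage markers, appended exact (optionally noisy) duplicates of
  random markers, and an NTC table in which a chosen fraction of markers
  fluoresce above the 0.2 threshold. A truth record names every injected
  defect so the QC cascade can be audited defect-by-defect.

What passing tests on these data do **not** show: robustness to linked
markers (no LD), to genotyping error correlated with genotype cluster
geometry (missingness is uniform), or to unbalanced and structured "other"
populations (the non-target side is a single random-mating population per
simulation).

## Estimators

**Pool-seq F<sub>ST</sub>** (marker discovery) is the Hudson-form
two-population estimator with a pool-seq effective sample size
`n_eff = n_c·d/(n_c+d−1)` — the number of independent allele draws a pool
of `n_c` gene copies sequenced to depth `d` provides:

```
FST = [(p̂1−p̂2)² − p̂1(1−p̂1)/(n_eff1−1) − p̂2(1−p̂2)/(n_eff2−1)]
      / [p̂1(1−p̂2) + p̂2(1−p̂1)]
```

This form was chosen over an ANOVA-style estimator because it is
closed-form, well-conditioned for two groups, and the pipeline uses it
purely as a ranking statistic. The one-to-many contrast sums read counts
(not frequencies) over the non-target pools, weighting pools by their
observed depth, and adds their haploid sizes. SNPs with zero depth on
either side, `n_eff ≤ 1`, or both sides fixed for the same allele are
reported as undefined rather than clamped.

**Individual-genotype F<sub>ST</sub>** (divergence monitoring) is
Weir–Cockerham (1984) θ from the a/b/c variance components; the test suite
carries an independent scalar re-derivation as an oracle. Negative
per-marker estimates are retained — truncation at zero would bias the
baseline-vs-novel contrast. Multi-locus summaries are ratio-of-averages
(Σa / Σ(a+b+c)); a per-marker mean is also reported for transparency, and
a regression test pins the convention. The Hudson form on genotype
frequencies is provided as a cross-check estimator.

## Selection rules and quantile convention

* FST outliers: markers at or above an empirical quantile (default 0.99)
  of the defined per-SNP values; the threshold is exposed because outlier
  rules are dataset-dependent.
* PCA contribution: `score_j = Σ_k w_k·|L_jk|` over the first two
  components, with `w_k` the explained-variance fraction (an unweighted
  variant is provided). "Top contributors" defaults to scores at or above
  the 70th percentile of all scores; the alternative reading — the smallest
  top set carrying 70% of the summed contribution — is available as
  `mode="cumulative"`. PCA input is the sample × marker matrix (markers
  must be the variables for loadings to exist per marker); centering on,
  scaling off, since dosages share a scale.
* All quantiles use numpy's linear interpolation between order statistics.

## QC cascade

Order: call rate → NTC → sample missingness → monomorphic →
near-zero variance → correlation pruning. Boundary semantics follow the
deployed assay's printed rules exactly: call-rate drop is inclusive
(≤ 0.80), NTC and missingness drops are strict (> 0.2, > 0.20). Near-zero
variance uses the conjunctive frequency-ratio (> 19) and unique-percent
(< 10%) rule familiar from the caret ecosystem; correlation pruning is a
deterministic greedy loop on pairwise-complete |Pearson r| (> 0.90) that
removes, from the worst pair, the member with the larger mean absolute
correlation (ties: the later-indexed marker). Pairs with fewer than three
complete observations get correlation 0 and a log entry. Every drop is
recorded with marker/sample id, rule and triggering value; an empty panel
after any stage raises an error naming the stage.

## Classification

Dosage matrices are mean-imputed per marker (imputed values stay inside
[0, 2]); prediction reuses the training means, so no test information
leaks. The stratified splitter holds out `floor(0.2·n)` per class. Tuning
runs leave-one-out cross-validation per (algorithm, parameter) combination
— imputation means are recomputed on each n−1 fold — and computes F-score,
accuracy and kappa once on the pooled out-of-fold predictions (per-fold
metrics are degenerate for single-sample folds). The winner maximises
F-score, with accuracy, then kappa, then grid order as tie-breaks.

Three algorithm families are configured natively behind one interface:
randomized-tree ensembles (scikit-learn `RandomForestClassifier` for the
gini split rule, `ExtraTreesClassifier` for extremely randomized
thresholds; `mtry` → `max_features`, minimum node size →
`min_samples_leaf`; 500 trees by default; class probability = mean of
per-tree votes), Gaussian naive Bayes, and k-nearest neighbours. The full
tree grid (mtry 2–10 × 2 split rules × node size 2–10) enumerates 162
combinations.

Membership assignment is strict: a sample joins the target class only when
its probability exceeds the threshold (default 0.5); exactly 0.5 goes to
the other class. Metrics come from the 2×2 confusion matrix (rows known,
columns predicted, positive class first): accuracy, precision,
sensitivity, specificity, F (0 with a flag when no positive predictions
exist), Cohen's kappa from the marginals, and a Pearson chi-square of
independence with Yates continuity correction
(`X² = n(max(|ad−bc|−n/2, 0))²/[(a+b)(c+d)(a+c)(b+d)]`, df = 1) — the
corrected form reproduces the printed statistics for both the imperfect
(3.744) and the perfect (34.095) assignment tables on the 20/18 test
split, which the uncorrected form does not.

## Numerical and design choices

* Missing dosage is NaN in a float matrix: not a valid dosage code, and it
  propagates through arithmetic so it can never silently act as data. The
  CSV token is "NA" (configurable).
* Coordinates are 0-based half-open everywhere (BED convention); VCF
  positions are converted on read; GFF-style 1-based inputs are
  deliberately unsupported to avoid silent off-by-one drift. Touching
  interval endpoints do not overlap. A SNP inside a block hit by two
  amplicons counts once.
* Interval overlap is a per-chromosome all-pairs scan — panel-scale inputs
  are tens of amplicons against hundreds of blocks, where an index would
  add code without measurable benefit.
* PCA is computed by SVD of the centered matrix and oracle-checked against
  a dense eigendecomposition in the tests; loadings are unit-norm, sign
  unpinned (all downstream use is via absolute values).
* Determinism: every stochastic stage takes a seed; sub-streams are derived
  with `SeedSequence` so pools, genotypes and degradation are independent
  but reproducible. Identical seed + config + inputs give identical
  outputs.

## Problem sizes in the checks

The test-suite and acceptance-script simulations use the package's own
desk-scale defaults: divergence-recovery checks at 2000 markers and 100
individuals per population averaged over 5 seeds; selector-recovery checks
with 10 planted truly divergent markers (Balding–Nichols draws at F = 0.4
conditioned on a realised true-frequency FST ≥ 0.25 — an unconditioned
draw often realises little divergence at a single SNP, which would test
luck rather than the selector) among ~1000 null markers; classifier checks
at 81 markers and 80 training samples per class. The acceptance script's
simulated study uses a 100 + 91 baseline, a 20% stratified hold-out, the
extratrees configuration with 500 trees, and LOOCV at 100 trees.

## Known limitations

* No linkage disequilibrium in the simulator, so correlation pruning is
  exercised only by injected duplicates.
* NTC "cluster overlap" is interval membership against caller-supplied
  fluorescence ranges; 2-D fluorescence clustering of the raw instrument
  output is out of scope.
* The classifier panel is binary (target vs pooled others); multiclass
  stock assignment is not implemented.
* Pool-seq FST assumes equal contribution of individuals to the pool; real
  pools have unequal DNA representation, which inflates variance beyond
  the `n_eff` correction.
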
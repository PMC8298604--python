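# Methods

## Differential-expression engine

The engine is a deliberately small negative-binomial Wald workflow — enough
to give downstream procedures a calibrated (p, log2FC) table, and no more.

* **Gene filter.** Protein-coding genes with mean raw count strictly > 1 per
  sample. No independent filtering beyond this rule.
* **Normalisation.** Median-of-ratios size factors. Reference genes are those
  with strictly positive counts in every sample; there is no pseudo-reference
  fallback, so a matrix with no all-positive gene is an error. Note the exact
  equivariance property holds for *ratios* of size factors: scaling one
  sample's column by c multiplies its factor by c relative to the others (the
  per-gene geometric means absorb c^(1/n)).
* **Dispersion.** Per-gene method of moments on normalised counts,
  α̂ = max(floor, (s² − m)/m²), shrunk toward a least-squares a₀ + a₁/m trend
  with weight 0.5 (floor 1e-8). This is stability over fidelity: there is no
  empirical-Bayes machinery, and no claim of per-gene optimality.
* **Fit.** Per-gene NB log-link regression with offset log sⱼ and fixed
  dispersion, solved by IRLS vectorised across genes (batched p×p solves;
  linear predictor clipped to ±30 to keep degenerate genes finite).
  Convergence is a 1e-8 sup-norm step; non-convergent and all-zero genes are
  reported untested. Wald p-values use the normal tail — no t correction, no
  fold-change shrinkage.
* **Sign convention.** The contrast coefficient is log fold change of the
  second-listed level over the first (for quartile contrasts: high over low).
* **Outliers.** Cook's distance from the final IRLS weights,
  D = r²h/(p(1−h)²) with Pearson residuals and leverages from the weighted
  hat matrix; a gene is flagged when any observation exceeds 0.2 and is
  excluded both from testing and from the BH denominator.
* **Multiplicity.** Step-up Benjamini–Hochberg, written out rather than
  imported so the acceptance oracle can check it against the definition;
  missing p-values pass through without inflating m.
* **Quartile contrasts.** For continuous covariates, samples at or below the
  linearly interpolated Q1 versus those at or above Q3.

Binary contrast levels order lexicographically (second level is the
"treatment") unless `ContrastSpec.level_order` overrides.

Calibration: on a global-null synthetic cohort (2000 genes, 44 vs 187) the
raw-p fraction below 0.05 and planted log2FC = 1 recovery are computed by
`scripts/acceptance.py`; nothing here asserts numbers the scripts do not
compute. Composition caveat: median-of-ratios assumes most genes are not
differential, so planted fold changes are only recovered unbiasedly when the
affected genes are a minority (test fixtures plant ~5%).

## Confounder screen

Each panel covariate is tested *marginally*: binary covariates as a two-group
contrast, continuous ones as lowest-vs-highest quartile, with no adjustment
covariates. A covariate is flagged when strictly more than 5 genes pass
adjusted p < 0.01. Multi-level categorical and degenerate covariates are
skipped with a warning. Marginal screening mirrors the classic two-step
design and is a known statistical limitation (confounders that only matter
jointly are invisible); the pipeline feeds flagged covariates (plus batch)
forward into the case/control adjustment set, overridable.

## Randomised case/control null

Samples are partitioned uniformly at random into pseudo-case/pseudo-control
groups of the real design's sizes and the full unadjusted DE contrast is
rerun per iteration (size factors and dispersions depend only on the counts
and are computed once). Reported: per-threshold median and maximum
significant-gene counts, and each gene's mean raw p across iterations. One
master seed spawns per-iteration seeds, so results are bit-reproducible and
parallel-safe. The randomised runs omit adjustment covariates; users can
adjust if their design demands it.

Recurrent near-significant genes (smallest mean p, ties broken by gene id)
are tested for gene-set over-representation with a one-sided hypergeometric
tail against a user background (sets intersected with the background first),
BH across sets. Mechanistic note: co-regulated gene blocks violate the
per-gene NB error model under relabelling — their shared latent variation
makes tail p-values anticonservative — so they recur among the top mean-p
genes far above base rate. The synthetic-data tests reproduce this
qualitatively; no quantitative claim (e.g. "three expected false positives")
transfers from real, globally correlated data to the simulator.

## Co-expression metagenes

Expression (size-factor-normalised counts, optionally batch-regressed) is
filtered to well-measured stable genes (mean > 10 and CV < 0.15), the
unsigned correlation adjacency a = |Pearson|^β (β = 1 by default) is
converted to topological overlap, and the average-linkage tree on 1 − TOM is
cut at height 0.95; clusters under 50 genes are discarded. Metagenes are the
mean member-gene z-score per sample (zero-variance genes excluded with a
warning), so each metagene's grand mean is 0 by construction. Group
comparison uses Welch's two-tailed t-test (pooled-variance available via
`equal_var=True`) with BH across clusters.

Batch correction is a linear per-gene batch-mean regression — an explicit
simplification that removes additive batch offsets exactly and nothing more.

Separation caveat: with β = 1 and n samples, spurious correlations of order
√(2/(πn)) put a floor under topological overlap between unrelated genes
(≈ 0.05–0.1 at n = 231), so weakly separated modules can merge below the
0.95 cut height. The recovery tests therefore use well-separated planted
blocks; on real data β is the knob to raise when modules smear together.

## Biological age

* Age DE: lowest vs highest age quartile, unadjusted; positive log2FC =
  up with age.
* Scoring expression: log2(normalised counts + 1), winsorised per gene at
  mean ± 3 SD. Winsorisation is a single pass with bounds from the input
  moments — clipping shrinks the SD, so a second application can clip
  slightly further; only in-bounds data is a strict fixed point. (Iterating
  to a fixed point was rejected: on near-degenerate vectors it collapses the
  gene to a constant.)
* Signature: tested genes with p_adj < p-cut and |log2FC| > lfc-cut, signed
  by fold-change direction; minimum 10 genes to guard against spurious
  perfect correlations from tiny signatures.
* Scores: mean sign-aligned z per sample, z computed across all samples
  jointly — the only scaling under which per-sample means are comparable
  across groups.
* Grid search: default p grid {0.01, 0.05, 0.1} × |log2FC| grid
  {0, 0.3, 0.6, 1.0}, maximising Spearman against chronological age; ties
  prefer fewer genes, then the smaller p cutoff.
* Asymmetry test: OLS of score on age over *all samples pooled* (a single
  line, as one would draw on the joint scatterplot); residual > 0 is
  "above", exactly 0 counts as "below" (an arbitrary measurable tie rule,
  documented here); two-sided Fisher exact test on the groups × {below,
  above} table. The counts are invariant to affine rescaling of the scores.
* Fisher exact: full enumeration of the hypergeometric support, summing
  point probabilities ≤ the observed one within relative tolerance 1e-7.
  Both margins must be positive.

`BiologicalAgeClock` packages fit (quartile DE + grid search) and predict
(scoring) in sklearn form; note predict z-scores within the prediction
cohort, so scores are relative, not absolute ages in years.

## Synthetic cohorts

The generator emulates a 231-sample PBMC-style bulk RNA-seq cohort:
44 HC / 94 treatment-resistant / 47 treatment-responsive / 46 untreated;
gamma-Poisson counts with log-uniform baselines (5–500), log-normal
dispersions (median 0.05), and log-uniform size factors (0.7–1.4); ages
uniform on 25–50; sex, BMI and batch effects on disjoint planted gene sets
(defaults: 100 genes at 1.0, 0.5/SD and 0.5 log2FC respectively); 500 age
genes at ±0.5 log2FC per decade (per decade so planted effects are
commensurate with a quartile contrast, whose low/high groups sit roughly a
decade apart); and two 60-gene co-expression blocks driven by a shared
standard-normal latent factor per block and sample.

Design choices worth knowing:

* The ageing offset shifts the *effective* age feeding the age-gene term of
  cases only; metadata always records chronological age. This is exactly the
  accelerated-ageing alternative hypothesis.
* Continuous covariate and age terms are centred, so planted effects do not
  shift baseline expression.
* Block genes are drawn from the high-mean (300–600), low-dispersion (0.003)
  stratum with loading 0.15: the mean/CV co-expression filter keeps only
  stable, highly expressed genes, and a co-expression module the analysis
  can see must live in that stratum. Loading 0.15 in log2 units puts block
  CVs near 0.13 (inside the 0.15 cut) with within-block correlations ≈ 0.7.
* Identical seed ⇒ bit-identical outputs, including the truth ledger.

What the generator does **not** emulate: library-preparation artefacts, GC
and length bias, count outliers beyond NB tails, cell-type composition
shifts, and the dense global correlation structure of real transcriptomes.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated model, not performance on real cohorts — in
particular, real-data false-positive expectations (which hinge on global
correlation) are not reproduced quantitatively.

## Problem sizes and numerical choices

Tests and the acceptance script use 2000-gene, 231-sample cohorts (the
cohort's real shape; the gene count is a deliberately compact transcriptome),
200 cohort seeds for offset-detection power and 1000 simulations for the
type-I rate of the residual-asymmetry test. The type-I simulation draws
(score, age) pairs from a fixed model with random group labels — the
score-level null that count-level exchangeability induces — which isolates
the test's calibration from Monte-Carlo cost of resimulating counts.
IRLS ridge 1e-10, eta clip ±30, BH and TOM as defined above; dispersion
floor 1e-8.

## Known limitations

* Normal-tail Wald p-values are mildly anticonservative for small groups;
  acceptable at this cohort's sizes (44 vs 187), checked by the calibration
  acceptance bound.
* Marginal confounder screening (see above).
* The co-expression stage's β = 1 / cut 0.95 defaults require well-separated
  modules (see above).
* No surrogate-variable adjustment, no GLM likelihood-ratio tests, no
  fold-change shrinkage — by design, out of scope.
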
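# Methods

## Module discovery

A co-expression module is defined operationally: rank all probes by
Pearson correlation to a seed probe across all samples and keep the top
*N* (default 100; the analysis scripts use 30 to match the synthetic
module size).  Multi-seed modules (SPRY-M) intersect the per-seed top-*N*
sets.  Choices worth noting:

* **Signed r**, not |r|: module members are *co-expressed* with the seed,
  so anticorrelated probes do not qualify.  A `use_abs` flag exists for
  the alternative.
* **The seed probe is excluded from its own ranking** (its
  self-correlation is trivially 1) and from the membership unless
  `include_seeds=True`.  Published module counts do not settle this
  convention, so it is switchable.
* Zero-variance probes are excluded from rankings (correlation
  undefined), with the count logged.  Ties at the top-*N* cut break by
  lexicographic probe id so results are order-independent.
* All samples in the matrix enter the correlation by default (tumor and
  control samples alike); a `samples` argument restricts to a subset.

## Signature construction and nonnegativity

The classifier works on the union of module member genes, z-scored per
gene across samples.  NMF needs a nonnegative input, and the labeling rule
needs under-expression to survive the transformation, so each z-row is
**signed-folded** into a positive part max(z, 0) and a negative part
max(−z, 0).  Folding preserves over- and under-expression symmetrically,
unlike a global min-shift, which would encode under-expression only as
"small positive" and blur the mirrored subtype patterns.  Zero-variance
genes are dropped (z undefined); fewer than two usable genes is an error.

## NMF and consensus clustering

`nmf_run` implements multiplicative-update NMF minimizing the generalized
Kullback–Leibler divergence D(V‖WH) = Σ V log(V/WH) − V + WH, with
uniform(0, 1] random initialization.  The updates provably never increase
the objective; every run's trace is asserted non-increasing (numerical
tolerance 1e-10 relative).  Defaults: `max_iter=2000`, `tol=1e-6`,
stopping after the relative objective decrease stays below `tol` for 10
consecutive iterations.  A machine-epsilon floor in the update
denominators guards against division by zero without perturbing the
fixed points.

Consensus clustering runs `n_runs` (default 50) factorizations from
seeds spawned off a master seed.  Each run assigns a sample to the argmax
row of H (ties to the lower index); run-level connectivity matrices
average into the consensus matrix C.  Final labels cut the
average-linkage tree of 1 − C into k groups, and the **cophenetic
coefficient** — the Pearson correlation between the 1 − C distances and
the tree's cophenetic distances — measures stability on that same tree,
so labels and stability derive from one object.  A constant distance
matrix makes the coefficient undefined; it is returned as NaN, flagged.
Rank selection beyond comparing ρ across k ∈ {2, 3, 4} is out of scope.

## Subtype orientation and the RMPA score

With two clusters, per-cluster centroids of standardized module
expression cast three votes: higher SPRY-M, lower NF1-M, lower PTEN-M.
The majority winner is RMPA-high; a 2–1 vote is accepted but logged as a
discordant pattern.  The continuous score per sample is

    score = mean z(SPRY-M) − ½ · (mean z(NF1-M) + mean z(PTEN-M)),

with the two repression modules half-weighted so that together they
balance the single induction module; the weighting is a package
convention, configurable by supplying different modules.
`hierarchical_split` applies average-linkage clustering on Euclidean
distances of the signature submatrix to split a sample subset (e.g. one
morphology group) in two, orienting the groups by mean score.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` behind a validated interface (times > 0, events ∈ {0,1},
exactly two non-empty groups, at least one event).  Tied deaths enter one
hypergeometric term; the p-value is two-sided from χ²(1).  Per-grade
stratification runs the test within each stratum with ≥2 subjects per
group and marks the rest "insufficient".  Samples missing time or event
are excluded pairwise with logged counts.  Cox regression and confidence
intervals for medians are out of scope.

## Copy number, dosage and alteration dependence

Copy-number states come from fixed, inclusive log2-ratio thresholds:
gain ≥ 0.25, loss ≤ −0.2, high-level gain ≥ 0.7, homozygous loss ≤ −1.1
(gain/loss = single-copy changes, high-level gain = two or more copies).
Segmentation and peak-detection tools that produce such ratios are
consumed, not reimplemented.  A sample carries an **arm-level** gain
(loss) when at least `arm_frac` (default 0.7) of the arm's genes are
called gain-or-higher (loss-or-lower); the per-sample rule is a package
decision, since published arm-level frequencies do not state one.

Gene-dosage effect is Spearman's rank correlation between a gene's
expression and its copy number (mid-ranks for ties); p-values use the t
approximation for n > 10 and a permutation null for n ≤ 10 (exhaustive up
to n = 7, 10,000 sampled pairings for n = 8..10).

Pairwise alteration dependence uses the odds ratio and the two-sided
Fisher exact test under the "tables no more probable than the observed"
convention (conventions differ between tools, so this is stated
explicitly).  When any 2×2 cell is zero the odds ratio gets a +0.5
Haldane correction to every cell, with the raw infinite/zero value
reported alongside.  Verdicts at level α: co-occurring (p ≤ α, OR > 1),
exclusive-tendency (p ≤ α, OR < 1), else independent.
Benjamini–Hochberg FDR is reported across whatever pair set is tested.

## IHC scoring

IRS = percentage score × intensity grade.  Percentage bins: <10% → 1,
10–50% → 2, 51–80% → 3, >80% → 4; the printed bins leave (0.50, 0.51)
unassigned, and fractions there map to the upper bin (score 3) by
convention.  Intensity grades 0–3.  Group comparison is the unpaired
pooled-variance (Student) t test, with Welch available by flag; zero
pooled variance with equal means returns t = 0, p = 1, with unequal means
a flagged degenerate result.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes, with
one RNG stream per data layer (subtype, expression, survival, copy
number, alterations) spawned from a master seed so layers regenerate
independently.

* **Expression**: one latent factor per module.  Sample i in subtype z
  has factor f_m,i = ±δ (sign by module and subtype) + N(0, 1) jitter;
  member gene g has x_g,i = λ_g f_m,i + N(0, σ²), λ_g ~ U(0.5, 1.0) so
  top-N selection faces a correlation gradient, and the seed gene takes
  λ = 1 (the maximum).  Background genes are pure noise.  A +8 offset
  puts values on a log2-intensity-like scale.  Defaults: n = 200 samples,
  P(high) = 0.5, three 30-gene modules, δ = 1.5, σ = 1, 200 background
  genes.
* **Survival**: exponential event times, baseline median 36 months in the
  low-hazard subtype (rate h0 = ln 2 / 36 per month, a realistic glioma
  scale), hazard ratio 2.5 for RMPA-high.  Censoring is uniform(0, c)
  with c solved numerically so the expected censoring fraction matches
  the target (default 0.3).  The exponential/uniform pair is the simplest
  model with a controllable hazard ratio; the analyses themselves are
  nonparametric.
* **Copy number**: per-sample arm events — chr7 gain with probability
  0.8/0.15 (high/low subtype), chr10 loss 0.75/0.2 — set integer copies
  (gain: 3, or 4 with probability 0.25; loss: 1, or 0 with probability
  0.1) for the 12 genes placed on 7p/7q/10p/10q; log2 ratios are
  log2(copies/2) (floor 0.25 copies) plus N(0, 0.03) measurement noise.
  Each arm gene shadows one background expression gene whose expression
  shifts by dosage_beta × (copies − 2), default 0.8.
* **Alterations**: one exclusive pair (target OR 0.2) and one
  co-occurring pair (target OR 5.0) drawn per sample from a 2×2
  distribution with 0.35 marginals and the exact target odds ratio
  (Plackett construction); remaining genes are independent Bernoulli(0.2).

What the generator does **not** emulate: platform/batch effects across
cohorts, tumor-microenvironment cell mixtures, non-proportional hazards,
within-arm segmentation breakpoints, and correlation between alteration
pairs and expression subtype.  Tests passing on these cohorts show the
pipeline recovers the assumed structure at realistic noise; they do not
certify behavior under real-data artifacts outside that structure.

## Problem sizes in tests

The test suite and acceptance script regenerate everything they measure:
cohorts of n = 150–500 samples, 10 master seeds for recovery checks,
2000 replicates for log-rank null calibration, 500 for the power check,
consensus NMF with 50 restarts at k = 2 (20 at k = 3, 4).  These sizes
were chosen to make the planted-effect checks statistically stable while
keeping a full run in the minutes range on one core.
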
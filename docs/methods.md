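# Methods

## Task and feature model

The questionnaire consists of eleven sentences, each pairing one of
seven adverbs of time (last week, yesterday, today, now, this week,
tomorrow, next week) with a verb in past or present tense; respondents
place the described event on a nine-point scale (1 far past, 5 present,
9 far future). Sentence metadata enforce the grammatical pairing used
in the task: future adverbs take the present tense (items 1, 4, 8),
past adverbs the past tense (3, 6, 7, 10), and present adverbs either
tense (2, 9 present; 5, 11 past).

The **standard response** is the per-sentence mean among non-demented
participants, with sample SD (n−1 denominator; a single observation is
reported as SD 0 with a flag). Sorting the eleven sentences by
ascending standard score recovers the nominal past-to-future ordering
of the adverbs; the package ships the published means (2.5 … 7.2) and
SDs (0–0.75) as reference constants, sentence No. 5 ("now" + past
tense) anchoring the scale at exactly 5.

Each participant's scores y are fitted against the standard scores x by
a line constrained through the pivot (5, 5), y = k(x−5)+5. The slope
has the closed form k̂ = Σ(x−5)(y−5)/Σ(x−5)², and the determination
coefficient is 1 − SS_res/SS_tot about the mean of y. Conventions where
the definition is genuinely open:

* negative raw determination coefficients (a constrained line can
  explain less than the mean) are clamped to 0 for the clustering
  plane; the raw value is retained in the feature table for audit;
* constant responders have SS_tot = 0, so the coefficient is
  mathematically undefined; they keep their slope but are excluded from
  clustering with reason `constant_response` rather than being assigned
  an arbitrary 0;
* participants missing any of the eleven items are excluded with reason
  `incomplete` (analysis stages, not the loader, decide exclusion).

## Clustering

The (slope, dc) points are fitted with full-covariance Gaussian
mixtures (both axes are O(1), so no standardisation is applied;
tilted ellipses require full covariances). EM uses 50 restarts,
log-likelihood tolerance 1e-6, and is deterministic given the seed.
Hard labels are maximum-posterior assignments; components are
relabelled by increasing distance of their mean from the
intact-response point (1, 1), so "cluster 1" is always the near-normal
cluster regardless of EM initialisation order.

K is selected from 2–6 by maximising the mean silhouette (Euclidean
distance on the raw plane), ties resolved toward the smaller K. The
silhouette is computed in-house because the convention used here —
singleton clusters contribute s = 0, including the all-singleton limit
— is not reachable through the scikit-learn API at the boundary; the
implementation is tested against both a brute-force pairwise oracle and
scikit-learn on generic inputs.

Each component is drawn as its confidence ellipse with Mahalanobis
radius √χ²(c; 2) (2.447 at c = 0.95). Pairwise ellipse overlap is
quantified as intersection area over the smaller ellipse's area by grid
integration (400×400 over the joint bounding box), validated against
Monte Carlo within 0.01.

## CBF quantification and aggregation

The Patlak transform maps a dynamic curve to xs(t) = ∫₀ᵗ CP dτ / CP(t)
(reported in minutes) and ys(t) = CT(t)/CP(t); the linear portion has
slope K₁ (1/min) and intercept V₀. Numerical choices: trapezoidal
quadrature on frame midpoints, with the integral below the first
midpoint taken as a rectangle at the first frame's value (so a constant
input integrates exactly to CP·t); the default fit window is the frames
where xs exceeds 40% of its final value — a simple, logged proxy for
the late linear portion, overridable by an explicit frame range. The
transform agrees with adaptive quadrature to < 1e-3 of the plot range
at 1-s framing, and parameter recovery is exact in the noiseless linear
model by construction.

Territory values are area-weighted means of constituent ROIs. The real
636-ROI stereotactic template is proprietary, so the package bundles a
synthetic toy template (4 ROIs per hemisphere-territory, unequal areas)
that exercises the weighted aggregation; region numbering follows the
display convention in which the right/left pericallosal territories are
regions 15/16. Optional global normalisation divides by the all-ROI
area-weighted mean.

## Group statistics and discriminant search

Demographic and regional comparisons use classical equal-variance
one-way ANOVA (no Welch correction) followed by Tukey–Kramer pairwise
tests (scipy's studentized-range implementation, cross-checked against
statsmodels). The regional screen runs one ANOVA per territory and
declares significance at alpha/m with m = 24; in strict mode (default)
a region missing for any labelled participant is an error, otherwise it
is dropped from the report.

Cluster prediction uses Gaussian LDA with pooled within-class
covariance and empirical class priors (switchable to uniform). If the
pooled covariance is singular, a ridge of 1e-8 · trace/g is applied and
logged; a zero-trace covariance remains an error. Leave-one-out
validation refits from scratch per fold; folds whose training set loses
a class predict among the remaining classes and are logged. The
exhaustive search evaluates all 24 single-region models and all 276
pairs, ranked by hit rate with ties broken by region-id order so the
reported best model is reproducible.

A note on chance levels: with empirical priors, leave-one-out on
label-permuted (null) data is systematically pessimistic — the held-out
sample's class is under-represented in its training fold — so the
chance-level calibration check uses the uniform-prior switch, where the
null hit rate is 1/3 for three balanced classes.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not any individual dataset:

* **linear** regime (default n = 20): per-participant slope ~
  N(1.0, 0.10), response noise SD 0.4;
* **coarse** regime (n = 15): items collapsed to 1/5/9 by the adverb's
  nominal category, with probability 0.05 of misgrading into an
  *adjacent* category, plus noise SD 0.5. Noiseless coarse scoring of
  the reference standard yields slope ≈ 2.3, comfortably above the 1.5
  that characterises the steep cluster;
* **flat** regime (n = 20): responses ≈ pivot + 0.35·(x−5) with noise
  SD 1.1, giving slopes below 1 and low explained variance.

Scores are rounded half-away-from-zero and clipped to 1..9. Noise
scales were calibrated once against the spread of the published
standard response (per-item SDs 0.41–0.75) and the qualitative cluster
geometry (steep cluster slope > 1.5 with dc > 0.5; flat cluster slope
< 1 with dc < 0.6); two generator design points matter and were fixed
at design time: misgrades move to adjacent categories (whole-scale
flips create a spurious fourth cluster of low-dc coarse responders),
and the flat regime keeps enough item dependence that the dc ≥ 0 clamp
does not produce a degenerate point mass at zero. At these defaults the
silhouette criterion selects K = 3 and cluster–regime agreement
exceeds 0.9.

Regional CBF is Gaussian per region (SD 4.5 ml/100 g/min) around
territory baselines (38–54 ml/100 g/min) minus a cluster decrement
(0/3/6 generally; 0/7/14 in the pericallosal territory), so blood flow
declines over clusters 1 → 2 → 3 everywhere with the sharpest contrast
pericallosally. Demographics (MMSE, response time, CDR consistent with
group) are simple cluster-conditional Gaussians for the summary tables.

What the generator does **not** emulate: item-level response
correlations beyond the regime mean structure, inter-regional CBF
correlation (regions are conditionally independent given cluster),
scanner effects, and any coupling between response noise and
demographics. Passing tests therefore demonstrate that the pipeline
recovers structure of this idealised form, not that it would find the
same regions in new clinical data.

## Problem sizes and determinism

Default analysis sizes: 55-participant cohorts (20/15/20), K searched
over 2–6 with 50 EM restarts, 300 discriminant models with n ≈ 30–55
leave-one-out folds. Simulation-based checks use 200 replicates for
regression/Patlak parameter recovery and the permutation null, 1000
replicates for the family-wise error of the Bonferroni screen, and 50
generator seeds for the pericallosal ranking property. All randomness
flows through explicit integer seeds; pipeline stages derive
independent substreams from the global seed, and identical
configuration yields byte-identical outputs.

## Known limitations

* The silhouette landscape on real two-feature data can be flat across
  K; the reported silhouette-vs-K trace should be inspected rather than
  trusting the argmax blindly.
* The dc clamp discards information about how badly the constrained
  line fits; the raw value is exported but not used downstream.
* The Patlak "linear portion" heuristic assumes the late frames are
  linear; tracers or framing where that fails need an explicit window.
* LDA assumes shared within-class covariance; with 8–14 participants
  per cluster, covariance estimates are noisy and hit rates optimistic
  relative to an external validation cohort.
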
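# Methods

This note documents the models, conventions and design choices behind
`opinionet`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Stances and the bipartite graph

A Likert response *x* on a scale [min, max] is trichotomized against the
scale midpoint *m* = (min + max)/2: stance = sign(*x* − *m*) ∈ {−1, 0, +1},
missing propagates. On even-length scales (e.g. the 1–4 trust items) the
midpoint is unattainable, so every answered item yields a non-neutral
stance; on odd-length scales (1–7) the midpoint response is neutral.
Custom per-item cutpoints are available where midpoint splitting is not
appropriate.

The bipartite graph has person and item nodes; one signed edge per
non-zero, non-missing stance. Persons with all-neutral rows remain as
isolated nodes. Edges never connect nodes of the same type by construction.

## 2. Projections

**Participant projection.** For persons *i, j*:
`compared` = #items with both stances non-zero and non-missing;
`shared` = #compared items with equal sign; weight *w* = shared/compared.
An edge (weight *w*, support = compared) is emitted iff
compared ≥ `min_overlap` (default 5) and *w* ≥ `threshold` (default 0.75).
Agreement is sign agreement after binarization, not raw-value equality:
the weakest rule realizing agree/disagree semantics. Neutral stances count
neither as agreement nor disagreement — a midpoint response is neither
trust nor distrust.

**Attitude projection.** For items *a, b*: *C* = #persons with
s<sub>a</sub>·s<sub>b</sub> = +1, *D* = #persons with
s<sub>a</sub>·s<sub>b</sub> = −1. An edge is emitted iff *C* ≠ *D*, with
sign = sign(*C* − *D*), weight = |*C* − *D*| and support = *C* + *D*. Net
counts carry the majority (mostly-agree / mostly-disagree) semantics while
the support field retains the raw count for audit.

Both projections are computed by vectorized Gram-matrix identities
(compared = |S||S|ᵀ with missing/neutral zeroed; shared = (SSᵀ + compared)/2)
and are checked in the test suite against deliberately naive double-loop
reference implementations (`opinionet.reference`) for exact agreement on
random stance matrices. The threshold comparison uses a 1e-9 additive slack
on the integer inequality `shared ≥ threshold·compared` so that weights
exactly at the threshold are kept regardless of floating-point
representation.

`threshold_edges` retains edges with weight ≥ threshold and keeps all
nodes; `bridging_edge_count` counts edges whose endpoints carry different
faction labels and errors on unlabelled nodes.

## 3. Faction detection

The default faction rule is **connected components of the thresholded
participant projection**, numbered by decreasing size (ties broken by the
smallest contained participant id, so numbering is deterministic). With
`keep_largest=2`, participants outside the two largest components are
marked unassigned — the minimal formalization of "two visually evident
clusters". Components are deliberately simple; modularity or block-model
community detection is out of scope because the downstream semantics
(bridging edges between two camps) presuppose a hard two-way split.

Cross-validation uses k-means (scikit-learn, squared Euclidean, best of
`n_restarts` inertia, fixed seed) on **raw Likert values** — the attitude
items share one scale, so standardization is unnecessary; a `standardize`
flag exists for mixed-scale use. Clusters are renumbered by decreasing
size. Partition agreement is reported as a contingency table, a Pearson χ²
independence test (no continuity correction by default, matching
large-sample usage; available as a flag) and the adjusted Rand index.

Semantic labels: the cluster with the higher mean stance on anchor items
(defaults: trust in science, trust in scientists) is the *truster* cluster,
the other the *sceptic* cluster; an exact tie raises and demands manual
labels rather than guessing.

## 4. The synthetic cohort generator

The generator plants structure; it does not model opinion dynamics.
Participants receive a fixed faction (default split 0.6/0.4 of n = 300).
Attitude items divide into 7 *shared* items (both factions' stance template
is +1) and 4 *contested* trust items (science, scientists, government,
journalists). Faction 1's contested template flips to −1 at wave *t* when
the item's single uniform draw u<sub>item</sub> ≤ d<sub>t</sub>, where
d = (0.2, 0.5, 0.9) is the divergence ramp. Holding u fixed across waves
makes the flipped set nested under a non-decreasing ramp, so the expected
between-faction stance gap on contested items is monotone wave over wave —
the property the pipeline is meant to detect.

Each response matches its faction template with probability
c = `consensus_strength` (default 0.85), is opposite with probability
(1 − c)(1 − `neutral_rate`), and sits at the scale midpoint otherwise
(`neutral_rate` defaults to 0 and only applies on scales with an attainable
midpoint; the 1–4 trust scale has none). Integer responses are drawn
uniformly from the template-consistent half of the scale — the simplest
model preserving sign structure, which is all the network stage consumes.

Compliance (3 items) and epistemic clarity (3 items, both 1–7) are
generated from a Gaussian latent: persistent per-participant offset
(sd 1.0) plus per-item occasion noise (sd 1.3 / 0.8), rounded and clipped.
Faction 1's latent mean is lower by `behaviour_effect_d` (default
Cohen's d = 0.3) **measured on the k-item scale-score sd**
√(subject_sd² + sd²/k), so the planted effect is the effect the group
tests estimate; d = 0.3 corresponds to η² ≈ 0.02, the magnitude such
studies report. Attrition removes each surviving participant with
probability 0.05 per wave (monotone panel: nobody returns), and 1% of
attention checks fail per wave, drawing a random wrong response.

Everything derives from a single `numpy.random.default_rng(seed)` stream:
identical seeds give bit-identical cohorts.

What the generator does **not** emulate: item-level covariance beyond the
faction structure (real attitude items correlate within person), ordinal
response styles (acquiescence, extreme responding), informative attrition
(dropout is independent of faction and attitudes), and any influence
mechanism by which divergence arises. Tests passing on this cohort
therefore validate the *pipeline's mechanics and statistics*, not
substantive conclusions about any real population.

## 5. Statistical conventions

* Descriptives: sample (n−1) standard deviation, matching M(SD) reporting.
* Scale scores: per-participant mean over available (non-missing) items;
  Cronbach α = k/(k−1)·(1 − Σ item variances / total-score variance) over
  complete cases only, with the complete-case count recorded. α is
  undefined (raises) for fewer than two items or zero total variance.
* One-way ANOVA: explicit SSB/SSW decomposition; η² via
  F·df₁/(F·df₁ + df₂), which equals SSB/(SSB + SSW) identically for
  one-way designs. Both groups constant raises; zero within-variance with
  non-zero between returns F = ∞, η² = 1.
* η² confidence interval: invert the noncentral-F cdf in the
  noncentrality λ (Brent's method on a bracketed, monotone function;
  bounds where the observed F sits at the (1 ± level)/2 quantiles), then
  map λ → η² via **λ/(λ + df₁ + df₂ + 1)**. The mapping is isolated in one
  helper so the alternative λ/(λ + N) convention can be swapped; for
  one-way designs the two coincide (df₁ + df₂ + 1 = N). Lower bound
  floored at 0.
* Wilks MANOVA: Λ = det(E)/det(E + H) from explicit cross-product
  matrices; Rao's F approximation (exact for ≤2 outcomes or ≤2 groups);
  multivariate η² = 1 − Λ^(1/s), which reduces to 1 − Λ for two groups and
  to the ANOVA η² for one outcome. Singular E raises with advice. For
  repeated measures the package takes the multivariate route: group
  effects on per-subject means, group×time interactions via
  `difference_scores` (successive-wave changes) fed to the same MANOVA —
  chosen over sphericity-corrected univariate ANOVA because the
  multivariate statistics (Λ) are what such analyses report.
* Logistic regression: maximum likelihood via statsmodels' Newton/IRLS
  iterations (tol 1e-8), Wald SEs from the inverse information matrix,
  OR = exp(B) with Wald CIs exp(B ± 1.96·SE), likelihood-ratio model χ²
  against the intercept-only model, percent correct at the 0.5 cutoff.
  CIs are computed from unrounded coefficients; recomputing a published
  interval from *rounded* B and SE can disagree in the last digit, which
  is why the implementation never tunes to printed intervals. Perfect or
  quasi-perfect separation raises.
* χ² independence: Pearson Σ(O−E)²/E with margin-product expectations,
  df = (r−1)(c−1); Yates correction opt-in for 2×2.
* Pearson correlation: two-sided p from the t transform with n−2 df.
* All p-values two-sided; no multiple-testing correction is applied by
  default (fidelity to common single-test reporting); callers can apply
  Holm or similar downstream.

## 6. Problem sizes used in validation

The test suite and reproduction script run at desk scale, chosen as the
smallest sizes at which each property is informative: 50 random
20-person × 8-item matrices for projection-oracle equivalence; 20 seeds of
the default n = 300 cohort for recovery and bridging trajectories; 2000
replicates of a 3×20 one-way design for CI coverage (true η² = 1/7);
n = 5000 for logistic recovery; 60 seeds at n = 228 for the planted-η²
recovery band.

## 7. Known limitations

* **Component separation needs high consensus.** With 11 attitude items,
  the participant-projection weight takes only 12 values, and the binomial
  overlap between within- and between-faction agreement distributions is
  large. At the default consensus c = 0.85 and threshold 0.75 the
  thresholded graph stays one giant component at every wave — thousands of
  cross-faction pairs clear 9/11 agreements, and a single bridging edge
  merges components — so component-based detection cannot recover the
  planted factions at those settings (the reproduction script reports the
  measured ARI and bridging counts). Clean component splits require either
  near-deterministic consensus (c ≳ 0.99 with a threshold above 10/11, as
  in the README example), many more items, or a detection rule robust to
  stray bridges. The k-means cross-validation route degrades far more
  gracefully and remains informative at moderate consensus.
* Bridging-edge counts are reported against whatever labelling is supplied
  (planted factions in validation); with detected labels they are biased
  low by construction since components cannot bridge.
* Rao's F is approximate for >2 outcomes with >2 groups; p-values there
  are asymptotic. The permutation check in the test suite bounds the
  discrepancy only for the sizes tested.
* The force-directed layout is deterministic per seed but its geometry has
  no statistical interpretation; only the component structure does.
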
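# Methods

## The problem

Given several omics matrices (e.g. mRNA expression, miRNA expression, DNA
methylation beta values) measured on one patient cohort together with
right-censored survival data (follow-up time `t`, event indicator `e`),
`omicsurv` (a) discovers molecular subtypes that are *ordered by survival*
— label 0 is always the worst-prognosis group — and (b) turns the subtypes
into a classifier that can label new patients, including patients with
only one omic measured or measured on a different platform.

## Pipeline

Each ensemble member is fit on a random 80% subsample of the cohort:

1. **Rank/distance normalization (per omic).** Keep the 100
   highest-variance training features. Within each sample, replace feature
   values by their within-sample rank divided by 100. Compute the n x n
   Pearson correlation matrix of these rank profiles, set d = 1 - r, and
   rank-normalize each sample's distance vector to [0, 1] (nearest training
   sample = 1.0, farthest = 0). Every sample is thereafter described by its
   distances to the n training samples, which is what makes cross-platform
   and partial-feature prediction possible: a new sample only needs some
   shared features to be placed relative to the training cohort.
2. **Autoencoder embedding (per omic).** A one-hidden-layer autoencoder,
   reconstruction `tanh(W' s(W v + b) + b')` with `s = tanh`, bottleneck
   h = 100, trained 10 epochs with Adam (lr 1e-3), 50% dropout, gradient
   clipping at global norm 5. Because the output activation lives on
   [-1, 1] and inputs on [0, 1], the output is mapped through (y + 1)/2 and
   trained with element-wise binary cross-entropy (this also makes the
   output-layer gradient exactly 2(y_hat - x), which cannot blow up).
   Weight dropout (zeroing entries of W, W') and an MSE loss are available
   behind flags; a PCA projector is a drop-in linear backend.
3. **Survival screening of latent features.** Each of the h latent features
   of every omic is tested with a univariate Cox proportional-hazards
   model; features with likelihood-ratio p < 0.01 from all omics are
   concatenated into Z.
4. **Subtyping.** Gaussian-mixture clustering on Z (diagonal covariance,
   up to 1000 EM iterations, best of 100 seeded initializations;
   k-means and an L1-Cox median split are alternatives). Clusters are
   relabeled by Kaplan-Meier median survival, ascending, so label 0 is the
   worst; when a KM curve never crosses 1/2 the restricted mean survival
   time (horizon = last observed time) substitutes, because a naive median
   of observed times is biased under censoring. Median ties are broken by
   group size (smaller group ranked worse), then raw label.
5. **Classifier.** Per omic, the 50 features of the top-variance set with
   the smallest Kruskal-Wallis p against the subtype labels form the
   training matrix M (entries are within-omic ranks over the kept set).
   An SVM is chosen by 5-fold cross-validated grid search over
   kernel in {linear, rbf}, C in {0.1, 1, 10, 100} and, for rbf, gamma =
   scale-heuristic x {0.1, 1, 10}; ties prefer the smaller C (stronger
   regularization, earlier grid position). Probabilities come from Platt
   calibration (per-class sigmoid on cross-validated decision scores,
   renormalized). A new sample sharing only a subset of omics/features
   triggers a reduced classifier re-fit on the restricted training data,
   cached per subset signature — no imputation.

**Member filtering and aggregation.** A member is eliminated when no latent
feature passed the survival screen or when its subtype labels are not
associated with survival on its training samples (log-rank p > 0.05).
Surviving members each emit a per-subtype probability vector for a sample;
the ensemble probability is their unweighted mean, matched on the
survival-ordered label index (weighting members by hold-out C-index is
available behind `RunConfig.weight_by_cindex`). The probability of subtype
0 is the sample's **risk score**; for K = 2 the final label is 0 iff that
probability exceeds 1/2, for K > 2 the argmax label is reported with the
risk score alongside.

**Evaluation.** Hold-out metrics are reported two ways, because both views
are informative and they answer different questions: the mean of per-member
metrics (how good is a typical member on its own 20%) and pooled
out-of-bag metrics (each sample's probabilities averaged over the members
that held it out, scored once against the cohort survival). K selection
fits the full ensemble for each candidate K in {2, 3, 4, 5} and keeps the
K with the best mean member silhouette, breaking ties by label stability
(mean pairwise ARI of member labelings); Kaplan-Meier coordinates are
exportable for the visual crossover check that cannot be automated well.

## Statistical kernel

The univariate Cox model is a dedicated Newton solver on the Efron partial
likelihood: the tie structure of a survival table is prepared once and
shared by all covariates, and each evaluation is O(n) in numpy. This
matters because a run performs tens of thousands of one-covariate fits
(h latents x omics x members x K candidates). The covariate is
standardized internally and the estimate rescaled; a constant covariate
returns a non-converged null result (coefficient 0, p = 1); a monotone
likelihood (perfectly separating covariate) is capped at |beta| = 50 and
flagged, its likelihood-ratio p remaining usable. The p-value is the
likelihood-ratio test (chi-square, 1 df); the solver is cross-checked
against lifelines in the test suite. The multi-group log-rank test
delegates to lifelines. Harrell's C is computed directly from its
definition — over pairs where the strictly shorter observed time had an
event, the fraction in which that sample has the higher risk, ties in risk
counting 1/2 — in chunked O(n^2).

## Synthetic cohorts

The generator plants exactly the structure the pipeline is built to find:
K subtypes assigned uniformly; per omic, `n_informative` features drawn
Normal(effect_size x subtype, 1) and the rest Normal(0, 1); a
methylation-like layer is squashed through a logistic map onto (0, 1).
Survival is exponential with hazard `baseline_hazard x HR^subtype`
(Weibull shape optional); censoring is independent exponential with its
rate solved (Brent) so the expected censored fraction hits the target.
Defaults are the package's standard study conditions: n = 200 samples,
2 subtypes, three layers (500/200/300 features with 50/20/30 informative,
effect size 1 SD), baseline hazard 1/1000 per day, hazard ratio 3,
censoring 20%. Paired cohorts for transfer experiments share a configurable
fraction of feature ids (the shared block comes first so informative
features are shared whenever the fraction allows) but are independent
draws.

What the generator does *not* emulate — and what passing tests therefore do
not certify about real data: count noise and library-size effects of
RNA-seq, batch effects, correlated feature blocks beyond the subtype
signal, non-proportional hazards, informative censoring, and within-subtype
survival heterogeneity. The last point has a concrete consequence: when
survival depends on the subtype alone, a subtype-based risk score cannot
exceed C = p_cross x HR/(1+HR) + (1-p_cross)/2 (~0.63 at HR = 3 with
balanced groups) no matter how good the clustering is, because within-group
pairs are coin flips. The pipeline reaches that ceiling on these cohorts;
higher C on real cohorts comes from risk gradients within subtypes that
the generator deliberately omits.

A second honest caveat: the member-retention filter is circular under the
null. Latent features are *selected for* survival association before
clustering, so even on pure-noise cohorts the training-label log-rank test
is significant for most members (~300 latent tests at alpha = 0.01 nearly
always pass at least one feature, and clustering on a spuriously selected
feature reproduces its association). Null behavior must therefore be judged
on hold-out metrics — which are well calibrated (pooled out-of-bag C ~ 0.5,
hold-out log-rank false-positive rate at the nominal level) — not on the
retained-member count.

## Numerical and design choices

- **Distance from correlation** is d = 1 - r; rank scores use average ranks
  for ties, then a linear rescale so each row attains 1.0 and 0 (a
  zero-spread row degrades to flat 0.5 with a warning). A training sample's
  self-distance is included and takes score 1.0, shared with exact
  duplicates through the tie handling.
- **Variance-selection ties** are broken by feature id (stable, auditable);
  duplicate feature rows on load keep the first occurrence with a warning;
  missing cells are rejected by default (per-feature median imputation
  behind a flag).
- **Sample order** is canonicalized to sorted ids at alignment so fits do
  not depend on input file ordering.
- **Determinism.** Every stochastic step (subsampling, autoencoder init
  and dropout, GMM initializations) draws from seeds derived from the
  top-level seed; identical (data, config, seed) reproduce bit-identical
  ensembles and predictions. Archives embed a schema version and round-trip
  predictions exactly.
- **Dropout semantics**: standard unit dropout on the hidden layer by
  default; zeroing 50% of the weight entries per step is available as
  `weight_dropout=True` — both realize a 50% rate, the unit form is the
  conventional one.
- **Degenerate inputs**: single-sample layers, all-identical feature
  matrices, single clusters, all-censored tables and empty sample
  intersections all raise typed errors; inside the boosting loop,
  "no survival features" and "labels not survival-associated" are recorded
  reasons, not exceptions, and only an ensemble with zero valid members
  fails.

## Problem sizes used in tests and the acceptance script

Statistical kernels are verified exactly against brute-force oracles
(100 C-index instances, 200 ARI pairs, direct silhouette, rank-test
p-values to 1e-10). Pipeline-level checks run on the standard synthetic
conditions above, with member/seed counts chosen per experiment (10-member
ensembles over 10 seeds for recovery; 50 null seeds; 5-member ensembles for
the hazard-ratio sweep and transfer; 3-member ensembles inside K
selection). `scripts/acceptance.py` reruns the same experiments with 3-10
seeds per quantity and prints medians.

## Known limitations

- With one CPU and default settings a 10-member fit on n = 200 takes a few
  seconds; K selection multiplies that by the candidate count.
- The L1-Cox dichotomization clustering backend supports K = 2 only.
- The co-expression edge score is |Spearman| (Pearson behind a flag); a
  tree-ensemble edge scorer is out of scope, so regulatory directionality
  is not modeled.
- Hold-out metrics are undefined (and flagged NaN) when a hold-out split
  contains no events or a single predicted class.
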
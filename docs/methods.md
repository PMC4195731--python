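# Methods

## Model

The package predicts a binary clinical outcome y ∈ {0, 1} (0 = alive,
1 = dead) from a features × samples expression matrix.  Its core premise is
that a single marker's expression x may relate to outcome risk
*nonlinearly*, so each feature is first passed through its own small
radial-basis-function network

    s(x) = bias + Σ_{h=1..H} w_h · exp(−‖x − c_h‖² / (2 σ_h²)),

trained with the 0/1 outcome as target and min–max rescaled (by its
training-output range) to a *score* in [0, 1].  The score is, by
construction, approximately linear in risk, so rank statistics on scores
(Spearman R, AUROC) become valid marker-selection criteria regardless of
the underlying expression–risk shape.

Selected markers are combined by a pyramid **cascade**: the k per-feature
score units form layer 0; integration units with fan-in f take the
normalized outputs of f lower units as inputs (again H hidden Gaussians)
and are trained greedily against the same outcome with the lower layers
frozen; layers repeat until one unit remains.  For k = 9, f = 3 this gives
layer sizes 9-3-1 and 13 units.  Flat baselines with a single wide unit —
UNN on raw normalized expression, TNN on per-feature scores, both over the
top-k features — quantify what the transformation and the cascade each
contribute.  Because every feature enters the cascade through its own
channel, corrupting one input can at worst disable one primary unit; a flat
network mixes the corruption into its only unit, which is the mechanism
behind the cascade's noise immunity.

## Unit training recipe

The original procedure used a commercial neural-network GUI whose
internals are undocumented, so the unit fit here is a standard,
deterministic, solver-free construction:

- **Centers**: k-means with k = H (default 11), 10 restarts, seeded.  When
  H ≥ n the data points themselves are the centers, which yields the exact
  RBF interpolant as ridge → 0.
- **Widths**: σ_h = max(distance to nearest other center, 1e-6) ×
  `width_scale` (default **3.0**).
- **Output layer**: ridge-regularized least squares of the 0/1 targets on
  the Gaussian design plus an unpenalized bias; `ridge` defaults to
  **10.0**.

The smoothing defaults matter.  A 1-D RBF fit with near-zero ridge and
nearest-neighbor widths has roughly one effective degree of freedom per
hidden unit; at cohort-scale n (≈ 200–300) it partially memorizes pure-noise
features and inflates their training-set score–outcome Spearman R to ≈ 0.18,
which buries genuinely informative nonlinear markers (whose marginal R under
realistic effect sizes is ≈ 0.2) in the upper tail of ~190 noise features.
With σ tripled and ridge at 10, null inflation falls to ≈ 0.10 while the
recoverable signal is essentially unchanged, and top-9 selection approaches
the ceiling attained by an oracle that knows the true shapes.  Both knobs
remain per-call arguments for users who want the interpolating limit.

Units are deterministic given (data, H, ridge, width_scale, seed); every
per-feature unit uses a child seed mixed from the global seed and the
feature index, so fitting a subset of features reproduces identical units.
The stored training-output range makes each unit self-contained: validation
outputs are mapped by the training calibration and clipped to [0, 1].
A unit whose training outputs have no spread is flagged degenerate and
scores a constant 0.5.

## Normalization and splitting

Min–max normalization is per feature.  By default calibration uses the
training samples only and validation values outside [0, 1] are clipped
(with a count recorded); calibrating on the whole collection — which leaks
validation extremes into the scale — is available as `legacy_calibration` for
reproducing the historical protocol.  Constant features map to 0.5, are
flagged, and are excluded from ranking; flat microarray probes are common
enough that erroring would be hostile.

Splits use largest-remainder apportionment (ties to earlier parts), so
312 samples at 2:1 give exactly 208/104 and 208 at 2:1:1 give 104/52/52.
Stratification (on by default) apportions the positive labels by the same
rule, so each part's class balance matches the cohort's up to integer
rounding, and the whole partition is a deterministic function of the seed.

## Ranking and evaluation choices

- Features are ranked by **signed** Spearman R (units are trained toward
  outcome 1, so informative features surface with positive R); `rank_abs`
  offers |R| ranking.  Ties break by higher AUROC, then feature id.  No
  multiple-testing correction is applied to the Spearman p-values —
  selection is by R magnitude, not significance — and the p-values use the
  large-sample t approximation.
- AUROC is the tie-corrected Mann–Whitney statistic; its SE follows Hanley
  & McNeil; paired model comparisons use DeLong's test (checked in the
  suite against a bootstrap oracle).
- Prediction-positive convention: score **≥** threshold.
- PPV at a criterion is the raw step function TP/(TP+FP) among reference
  samples at or above the criterion, with no smoothing; a criterion above
  every reference score is undefined (NaN).  Poor-prognosis probability for
  a new sample is the training-cohort PPV at that sample's score.
- Reported "accuracy" uses the Youden-optimal threshold on the training
  scores (the historical protocol's criterion is unstated), overridable.
- Internal validation follows the 2:1:1 holdout: per-unit Pearson
  correlations of unit output vs outcome on the training (Tr) and testing
  (Te) parts, plus model AUROC on the testing part.  The verification part
  is reported but unused — the closed-form fit has no early stopping to
  steer.
- The swap experiment substitutes already-normalized values (or uniform
  [0, 1] noise) into one feature at prediction time, without retraining or
  re-normalization.

## Cascade design choices

- Grouping of selected features into integration units is by consecutive
  Spearman rank ({1,2,3}, {4,5,6}, {7,8,9}); round-robin is available.
- A trailing singleton group is merged into its predecessor (an f+1-wide
  unit) rather than forming a pointless 1-input integration unit; a
  trailing pair forms a 2-input unit.
- Integration units consume the *normalized* scores of the layer below, so
  every unit's input domain is [0, 1]^d.
- Training is greedy layer-by-layer with frozen lower layers; the primary
  units are re-used from the feature-scoring stage (identical to retraining
  them, by determinism).  There is no end-to-end refinement.

## Synthetic cohorts

`generate_cohort` draws latent expression uniformly on [0, 1], computes the
risk logit as `logit(prevalence) + Σ β_f · g_shape(latent_f)` with shape
functions mapping [0, 1] → [−1, 1] (monotone: 2x−1; U-shaped: 8(x−½)²−1,
whose covariance with x is exactly zero; inverted-U: its negative; step:
sign(x−½)), draws Bernoulli outcomes, and records latent + Gaussian
measurement noise (sd 0.05, clipped) as the observed matrix.  Outcomes
depend on the *latent* values — noise is measurement error, not biology.

The benchmark spec uses 312 samples and 200 features (a desk-scale stand-in
for the motivating dataset's 873; the full width is one argument away),
nine planted features at β = 3 with a 3/2/2/2 mix of
monotone/U/inverted-U/step shapes, and baseline prevalence 0.35 — a
realistic event rate for a cancer-prognosis cohort of this size.  β = 3
places each marker's marginal rank correlation around 0.2–0.35: clearly
informative yet individually weak, which is the regime the method targets.

What the generator does *not* emulate: probe-level artifacts, batch
effects, correlated features, censored survival times, non-uniform
expression distributions (a lognormal option exercises normalization
nontrivially in tests).  Passing tests therefore demonstrate the machinery
and its comparative properties under the stated model, not performance on
any real dataset.

## Problem sizes in the test suite

Simulation-backed properties use 20 replicate cohorts of n = 300 with 10–40
features (single-feature and model-comparison checks) or the full n = 312 ×
200 benchmark (selection recovery), sizes at which the measured quantities'
replicate means are stable to well within the asserted margins.
`scripts/acceptance.py` averages 5 replicate benchmark cohorts per run.

## Known limitations

- Selection is performed on training data with the same units later used
  in the model; the score–outcome Spearman of every feature is therefore
  optimistically biased (roughly equally across features, which is why
  ranking still works).  On the 200-feature benchmark, ranking on the
  208-sample training half recovers ~5 of 9 planted markers (vs ≥ 7 on the
  full cohort): at half-cohort size, selection noise — not model capacity —
  limits the cascade, and its external advantage over the 3-marker TNN can
  vanish.  With more samples or stronger markers the ordering NNC ≥ TNN ≥
  UNN re-emerges, as the model-comparison tests show.
- Numerical agreement with models fitted by the original commercial
  software is not attainable and not claimed; the package reproduces the
  procedure, not its historical parameter values.
- The Spearman p-values and the DeLong normal approximation are
  large-sample; below n ≈ 30 treat them as descriptive.
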
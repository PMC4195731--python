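# nncascade

Neural network cascades of small radial-basis-function (RBF) units for
selecting **nonlinear expression biomarkers** and predicting a binary
clinical outcome (e.g. survival after cancer: 0 = alive, 1 = dead).

The package is aimed at anyone analyzing a feature-by-sample expression
matrix — bulk miRNA/mRNA microarray or similar — where the relationship
between a marker's expression and outcome risk may be non-monotone
(U-shaped, step-like), so that t-tests, fold changes and linear models miss
genuinely informative markers.

## The method

1. **Normalization.** Each feature is min–max scaled,
   `x' = (x − Min)/(Max − Min)`, with the per-feature Min/Max recorded so
   new samples normalize identically (training-set calibration by default;
   out-of-range validation values are clipped).
2. **Score transformation.** Every feature gets its own tiny 1-H-1 RBF
   network (H = 11 hidden Gaussians by default) trained against the
   outcome.  Its normalized output — the *miRNA score* `s(x) ∈ [0, 1]` — is
   approximately **linear in outcome risk** even when raw expression is
   not.  Training is deterministic and closed-form: k-means centers,
   nearest-center widths, ridge-regularized least-squares output layer.
3. **Ranking and selection.** Features are ranked by the Spearman
   correlation R of score vs outcome; the top k (default 9) are kept.  For
   a binary outcome with fixed class counts and untied scores, Spearman R
   is an increasing affine function of the AUROC, so either statistic
   selects the same markers.
4. **Cascade assembly.** The k selected score units form the primary layer
   of a pyramid; fan-in integration units (default 3 inputs each, also
   H = 11) combine their normalized outputs layer by layer until a single
   unit emits the death-risk score.  With k = 9, fan-in 3 the cascade has
   9 + 3 + 1 = 13 units.  Flat baselines — **UNN** (one 3-11-1 unit on raw
   expression) and **TNN** (the same on per-feature scores) — are included
   for comparison.
5. **Evaluation.** ROC/AUROC (Mann–Whitney with tie correction, Hanley–
   McNeil SE), DeLong paired AUROC tests, positive-predictive-value (PPV)
   calibration that converts any score into a probability of poor
   prognosis, 2:1:1 holdout validation with per-unit training/testing
   correlations (Tr/Te), and an input-swap experiment that corrupts one
   feature at prediction time to probe noise immunity.

A synthetic-cohort generator (`nncascade.simulate`) draws cohorts with this
exact structure — hundreds of samples and features, a few planted
informative features with monotone / U-shaped / inverted-U / step risk
shapes among many noise features — so the entire pipeline is testable
without any external download.

## Worked example

A cohort with one planted U-shaped feature (risk high at both expression
extremes, effect size β = 3, n = 300). Raw expression shows nothing; the
score transformation recovers the signal:

```python
import nncascade as nc

spec = nc.SimulationSpec(n_samples=300, n_features=10,
                         informative=[(0, "u_shaped", 3.0)], seed=3)
cohort, _ = nc.generate_cohort(spec)
norm = nc.normalize_expression(cohort, "all")
table = nc.transform_all_features(norm, seed=3)
rep = nc.expression_vs_score_report(norm, table, "feature_000")
```

```
raw expression: t-test p=0.453, AUROC=0.535
miRNA score:    t-test p=1.00e-21, AUROC=0.839
paired AUROC comparison p=5.27e-07
```

The dead/alive group means of raw expression are indistinguishable
(p = 0.45, AUROC ≈ chance) because high risk sits at *both* ends of the
expression range, yet the same feature's score separates the groups
decisively (AUROC 0.839); the DeLong test confirms the gain (p ≈ 5e-7).

Fitting the full cascade on the benchmark cohort (312 samples, 200
features, 9 planted markers):

```python
spec = nc.benchmark_spec(seed=7)
cohort, truth = nc.generate_cohort(spec)
train_raw, ext_raw = nc.split_cohort(cohort, (2, 1), seed=7)   # 208 / 104
cal = nc.normalize_expression(train_raw, "all").calibration
train, ext = (nc.apply_calibration(cal, c) for c in (train_raw, ext_raw))
table = nc.transform_all_features(train, seed=7)
ranking = nc.rank_and_select(table, train.outcome, k=9)
fitted = nc.fit_pipeline(train, nc.ModelSpec(kind="nnc", k=9), seed=7,
                         score_table=table)
```

```
    feature  spearman_r    auroc  rank
feature_151    0.333198 0.693262     1
feature_007    0.292331 0.669560     2
feature_179    0.284688 0.665127     3
units: 13 layers: [9, 3, 1]
external AUROC: 0.7264
AUROC after corrupting feature_151: 0.6364
```

The 13-unit cascade scores the 104 held-out samples at AUROC 0.726, and
replacing its top-ranked input with pure noise at prediction time costs it
only ~0.09 AUROC — the corrupted channel is one of nine, so the damage
stays contained (a flat 3-input network loses more; see the tests).

The same pipeline is available from the shell:

```bash
nncascade simulate --out cohort.tsv --seed 7
nncascade rank cohort.tsv --top-k 9 --seed 7 --out ranking.tsv
nncascade fit cohort.tsv --kind nnc --out nnc.json --seed 7
nncascade validate cohort.tsv --kind nnc --ratio 2:1:1 --seed 7
nncascade perturb cohort.tsv --model nnc nnc.json --target feature_151
```

To run the workflow on a real GEO Series Matrix file you have downloaded:

```bash
python scripts/reproduce_geo.py --series-matrix GSExxxxx_series_matrix.txt \
    --characteristic status --map alive=0 --map dead=1
```

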
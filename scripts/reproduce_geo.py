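#!/usr/bin/env python
"""Run the full workflow on a user-supplied GEO Series Matrix file.

This is an optional convenience for users who have downloaded a real
expression Series Matrix (e.g. a miRNA prognosis cohort) and want the
end-to-end analysis on it:

    python scripts/reproduce_geo.py --series-matrix GSExxxxx_series_matrix.txt \
        --characteristic status --map alive=0 --map dead=1 --seed 0

Nothing in the test suite or acceptance script depends on external data;
this script simply replays the pipeline: 2:1 split, training-set
normalization, per-feature scoring, top-9 Spearman ranking, NNC/TNN/UNN
fitting, internal 2:1:1 validation and external ROC/PPV evaluation.
"""

from __future__ import annotations

import argparse

import numpy as np

import nncascade as nc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--series-matrix", required=True)
    parser.add_argument("--characteristic", required=True,
                        help="characteristics field holding survival status")
    parser.add_argument("--map", action="append", required=True,
                        help="value=label pairs, e.g. alive=0 dead=1")
    parser.add_argument("--top-k", type=int, default=9)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--legacy-calibration", action="store_true",
                        help="calibrate normalization on the whole collection "
                             "instead of the training set only")
    args = parser.parse_args()

    value_map = {}
    for pair in args.map:
        key, _, label = pair.partition("=")
        value_map[key] = int(label)

    cohort = nc.load_geo_series_matrix(args.series_matrix, args.characteristic, value_map)
    print(f"loaded {cohort.n_features} features x {cohort.n_samples} samples "
          f"({int(cohort.outcome.sum())} events)")

    train_raw, ext_raw = nc.split_cohort(cohort, (2, 1), seed=args.seed)
    cal_source = cohort if args.legacy_calibration else train_raw
    cal = nc.normalize_expression(cal_source, "all").calibration
    train = nc.apply_calibration(cal, train_raw)
    ext = nc.apply_calibration(cal, ext_raw)

    table = nc.transform_all_features(train, seed=args.seed)
    ranking = nc.rank_and_select(table, train.outcome, k=args.top_k)
    print("\ntop-ranked features (training set):")
    for _, row in ranking.table.head(args.top_k).iterrows():
        print(f"  {int(row['rank']):3d}  {row['feature']:<20} "
              f"R={row['spearman_r']:+.4f}  AUROC={row['auroc']:.4f}")

    models = {}
    for kind, k in (("nnc", args.top_k), ("tnn", 3), ("unn", 3)):
        fitted = nc.fit_pipeline(train, nc.ModelSpec(kind=kind, k=k),
                                 seed=args.seed, score_table=table)
        models[kind] = fitted.model

    report = nc.internal_validate(train_raw, nc.ModelSpec(kind="nnc", k=args.top_k),
                                  seed=args.seed, legacy_calibration=args.legacy_calibration)
    print(f"\ninternal validation (2:1:1): testing-part AUROC {report.auroc_test:.4f}")

    s_train = nc.predict_model(models["nnc"], train)
    thr = nc.youden_threshold(s_train, train.outcome)
    curve = nc.roc_curve(s_train, train.outcome)
    print("\nexternal validation:")
    for kind, model in models.items():
        s_ext = nc.predict_model(model, ext)
        print(f"  {kind.upper()}: AUROC {nc.auroc(s_ext, ext.outcome):.4f}")
    s_ext = nc.predict_model(models["nnc"], ext)
    acc = float(np.mean((s_ext >= thr).astype(int) == ext.outcome))
    probs = nc.poor_prognosis_probability(curve, s_ext)
    print(f"  NNC accuracy at training Youden threshold {thr:.3f}: {100 * acc:.1f}%")
    print(f"  mean poor-prognosis probability: dead "
          f"{np.nanmean(probs[ext.outcome == 1]):.3f}, alive "
          f"{np.nanmean(probs[ext.outcome == 0]):.3f}")


if __name__ == "__main__":
    main()
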
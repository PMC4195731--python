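import numpy as np
import pytest

import nncascade as nc


@pytest.fixture
def tiny_cohort() -> nc.Cohort:
    """3 features × 4 samples with outcome (0, 1, 0, 1)."""
    return nc.Cohort(
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["fA", "fB", "fC"],
        expression=np.array(
            [
                [2.0, 4.0, 6.0, 3.0],
                [0.1, 0.9, 0.5, 0.2],
                [5.0, 5.0, 5.0, 5.0],  # constant
            ]
        ),
        outcome=np.array([0, 1, 0, 1]),
    )


@pytest.fixture
def separable_unit():
    """1-D unit trained on a separable step (y = 1 iff x > 0.5), n = 200."""
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 1, 200)
    y = (x > 0.5).astype(int)
    return nc.train_rbf_unit(x, y, seed=7), x, y


@pytest.fixture
def small_fitted():
    """A fitted 9-feature cascade + flat baselines on one synthetic cohort."""
    spec = nc.SimulationSpec(
        n_samples=240,
        n_features=24,
        informative=[
            (i, s, 3.0)
            for i, s in zip(
                range(0, 18, 2),
                ["monotone", "monotone", "u_shaped", "u_shaped", "inverted_u",
                 "inverted_u", "step", "step", "monotone"],
            )
        ],
        seed=11,
    )
    cohort, truth = nc.generate_cohort(spec)
    train_raw, ext_raw = nc.split_cohort(cohort, (2, 1), seed=11)
    train = nc.normalize_expression(train_raw, "all")
    ext = nc.apply_calibration(train.calibration, ext_raw)
    table = nc.transform_all_features(train, seed=11)
    fitted = nc.fit_pipeline(train, nc.ModelSpec(kind="nnc", k=9), seed=11, score_table=table)
    return {
        "cohort": cohort,
        "truth": truth,
        "train": train,
        "ext": ext,
        "table": table,
        "fitted": fitted,
    }


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_auroc(scores, outcome) -> float:
    """Exhaustive positive–negative pair counting; ties score 0.5."""
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, int)
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def rank_formula_spearman(a, b) -> float:
    """Tie-corrected Spearman via Pearson on midranks."""
    from scipy.stats import rankdata

    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def textbook_ttest(g1, g0):
    """Equal-variance two-sample t and two-sided p from the closed form."""
    from scipy.stats import t as tdist

    g1, g0 = np.asarray(g1, float), np.asarray(g0, float)
    n1, n0 = len(g1), len(g0)
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n0 - 1) * g0.var(ddof=1)) / (n1 + n0 - 2)
    t = (g1.mean() - g0.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    p = 2 * tdist.sf(abs(t), n1 + n0 - 2)
    return t, p
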
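"""Classifier pipeline: features, folds, metrics, leakage audit, bundles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from eaakit.classifier import (
    ClassifierBundle,
    TrainConfig,
    build_features,
    delong_ci,
    evaluate,
    fit_anchors,
    make_folds,
    roc_auc,
    train_pipeline,
    DEFAULT_ALPHA_GRID,
    DEFAULT_LAMBDA_GRID,
)
from eaakit.clocks import score_all
from eaakit.simulate import make_fixture_clocks, simulate_cohort
from eaakit.types import EaakitError

from conftest import hn_config


# ---------------------------------------------------------------------------
# metrics

def test_roc_auc_hand_counted_fixture():
    """pos {0.9, 0.8, 0.4} vs neg {0.7, 0.3, 0.2}: 8 of 9 pairs concordant."""
    y = np.array([1, 1, 1, 0, 0, 0])
    s = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
    assert roc_auc(y, s) == pytest.approx(8 / 9, abs=1e-12)


def test_roc_auc_limits():
    y = np.array([1, 1, 0, 0])
    assert roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
    assert roc_auc(y, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5  # ties = 1/2


def test_roc_auc_equals_curve_integration_and_mannwhitney():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n1, n0 = rng.integers(5, 40, 2)
        y = np.concatenate([np.ones(n1), np.zeros(n0)])
        s = np.round(rng.normal(size=n1 + n0), 1)  # ties on purpose
        mine = roc_auc(y, s)
        assert mine == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert mine == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_delong_ci_brackets_estimate_and_narrows():
    rng = np.random.default_rng(1)
    y = np.concatenate([np.ones(50), np.zeros(50)])
    s = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
    auc, lo, hi = delong_ci(y, s)
    assert lo < auc < hi
    y2 = np.concatenate([np.ones(500), np.zeros(500)])
    s2 = np.concatenate([rng.normal(1, 1, 500), rng.normal(0, 1, 500)])
    _, lo2, hi2 = delong_ci(y2, s2)
    assert (hi2 - lo2) < (hi - lo)


# ---------------------------------------------------------------------------
# features

@pytest.fixture(scope="module")
def hn_scored():
    cfg = hn_config(seed=19, n_datasets=4, samples_per_dataset=60)
    beta, sheet, gt = simulate_cohort(cfg)
    clocks = make_fixture_clocks(gt.clock_cpg_ids, gt)
    return sheet, score_all(beta, clocks)


def test_train_features_standardised(hn_scored):
    sheet, ss = hn_scored
    anchors = fit_anchors(ss.scores, sheet)
    X, y, scaler = build_features(ss.scores, sheet, anchors)
    np.testing.assert_allclose(X.mean(0), 0.0, atol=1e-8)
    np.testing.assert_allclose(X.std(0, ddof=0), 1.0, atol=1e-8)
    assert set(y.unique()) == {0.0, 1.0}
    assert "sex" in X.columns


def test_test_features_scaled_with_training_stats(hn_scored):
    sheet, ss = hn_scored
    anchors = fit_anchors(ss.scores, sheet)
    Xtr, _, scaler = build_features(ss.scores, sheet, anchors)
    Xte, _, _ = build_features(ss.scores, sheet, anchors, scaler)
    pd.testing.assert_frame_equal(Xtr, Xte)  # identical test set -> identical scaling
    # shifting one clock's EA by +10 moves its scaled feature by 10/sd exactly
    clock = ss.scores.columns[0]
    shifted = ss.scores.copy()
    shifted[clock] = shifted[clock] + 10.0
    Xsh, _, _ = build_features(shifted, sheet, anchors, scaler)
    delta = (Xsh[f"eaa_{clock}"] - Xte[f"eaa_{clock}"]).to_numpy()
    np.testing.assert_allclose(delta, 10.0 / scaler.sd[f"eaa_{clock}"], atol=1e-10)


def test_zero_training_sd_errors(hn_scored):
    sheet, ss = hn_scored
    anchors = fit_anchors(ss.scores, sheet)
    single_sex = sheet.copy()
    single_sex["sex"] = "female"
    with pytest.raises(EaakitError, match="sex"):
        build_features(ss.scores, single_sex, anchors)


# ---------------------------------------------------------------------------
# folds

def fold_sheet(class_map):
    rows = []
    for ds, tissues in class_map.items():
        for i, t in enumerate(tissues):
            rows.append(
                {"sample_id": f"{ds}_{i}", "patient_id": f"{ds}_{i}",
                 "dataset_id": ds, "age_years": 50.0, "sex": "female",
                 "tissue": t, "platform": "450k"}
            )
    return pd.DataFrame(rows).set_index("sample_id")


def test_fold_enumeration_matches_brute_force():
    """4 datasets with classes {H+N, H+N, H-only, N-only}: validity of all
    6 pairs checked against exhaustive enumeration."""
    class_map = {
        "A": ["healthy", "normal"],
        "B": ["healthy", "normal"],
        "C": ["healthy"],
        "D": ["normal"],
    }
    sheet = fold_sheet(class_map)
    plan = make_folds(sheet)
    # independent brute force
    from itertools import combinations

    expected = []
    for pair in combinations(sorted(class_map), 2):
        rest = [d for d in sorted(class_map) if d not in pair]
        test_cls = set().union(*(set(class_map[d]) for d in pair))
        train_cls = set().union(*(set(class_map[d]) for d in rest))
        if {"healthy", "normal"} <= test_cls and {"healthy", "normal"} <= train_cls:
            expected.append(pair)
    assert [p for p, _ in plan.folds] == expected
    assert len(plan.folds) + len(plan.invalid) == 6


def test_three_balanced_datasets_give_three_folds():
    sheet = fold_sheet({d: ["healthy", "normal"] for d in "ABC"})
    plan = make_folds(sheet)
    assert len(plan.folds) == 3


def test_two_datasets_error():
    sheet = fold_sheet({d: ["healthy", "normal"] for d in "AB"})
    with pytest.raises(EaakitError, match=">= 3"):
        make_folds(sheet)


def test_no_valid_fold_describes_missing_class():
    sheet = fold_sheet({d: ["healthy"] for d in "ABCD"})
    with pytest.raises(EaakitError, match="normal"):
        make_folds(sheet)


def test_default_grid_dimensions():
    assert len(DEFAULT_ALPHA_GRID) == 21
    assert len(DEFAULT_LAMBDA_GRID) == 101


# ---------------------------------------------------------------------------
# pipeline

SMALL_ALPHAS = (0.0, 0.5, 1.0)
SMALL_LAMBDAS = (0.02, 0.1, 0.5)


@pytest.fixture(scope="module")
def trained():
    cfg = hn_config(seed=33, n_datasets=5, samples_per_dataset=60, batch_sd=1.5)
    beta, sheet, gt = simulate_cohort(cfg)
    ss = score_all(beta, make_fixture_clocks(gt.clock_cpg_ids, gt))
    tc = TrainConfig(
        train_datasets=["DS00", "DS01", "DS02"],
        alpha_grid=SMALL_ALPHAS, lambda_grid=SMALL_LAMBDAS,
    )
    bundle, grid = train_pipeline(ss, sheet, tc)
    return sheet, ss, tc, bundle, grid


def test_training_is_deterministic(trained):
    sheet, ss, tc, bundle, _ = trained
    bundle2, _ = train_pipeline(ss, sheet, tc)
    assert bundle.to_json() == bundle2.to_json()


def test_no_sample_leaks_into_anchor_or_scaler(trained):
    """Leakage audit: every anchor and the scaler were fitted strictly on
    training-dataset samples."""
    sheet, ss, tc, bundle, _ = trained
    eval_ids = set(sheet.index[~sheet["dataset_id"].isin(tc.train_datasets)])
    for anchor in bundle.anchors.values():
        assert set(anchor.anchor_sample_ids).isdisjoint(eval_ids)
    assert set(bundle.scaler.fit_sample_ids).isdisjoint(eval_ids)
    assert set(bundle.train_sample_ids).isdisjoint(eval_ids)


def test_bundle_json_round_trip(trained):
    _, _, _, bundle, _ = trained
    back = ClassifierBundle.from_json(bundle.to_json())
    assert back.to_json() == bundle.to_json()
    assert back.alpha == bundle.alpha and back.lam == bundle.lam


def test_prediction_invariant_to_feature_column_order(trained):
    sheet, ss, _, bundle, _ = trained
    test_sheet = sheet[sheet["dataset_id"].isin(["DS03", "DS04"])]
    s1, _ = bundle.predict_scores(ss.scores, test_sheet)
    shuffled = ss.scores[list(ss.scores.columns[::-1])]
    s2, _ = bundle.predict_scores(shuffled, test_sheet)
    pd.testing.assert_series_equal(s1, s2)


def test_evaluation_rejects_overlapping_datasets(trained):
    sheet, ss, _, bundle, _ = trained
    with pytest.raises(EaakitError, match="overlap"):
        evaluate(bundle, ss.scores, sheet)  # includes the training datasets


def test_heldout_performance_with_planted_signal(trained):
    sheet, ss, _, bundle, grid = trained
    test_sheet = sheet[sheet["dataset_id"].isin(["DS03", "DS04"])]
    res = evaluate(bundle, ss.scores, test_sheet)
    assert res.roc_auc > 0.8
    assert res.roc_auc_ci[0] < res.roc_auc < res.roc_auc_ci[1]
    assert 0.0 < res.prevalence < 1.0
    assert grid.summary["mean_roc_auc"].max() > 0.8
    # chosen point is the tie-broken argmax of mean ROC-AUC
    best = grid.summary.sort_values(
        ["mean_roc_auc", "lam", "alpha"], ascending=[False, False, False]
    ).iloc[0]
    assert (bundle.alpha, bundle.lam) == (best["alpha"], best["lam"])
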
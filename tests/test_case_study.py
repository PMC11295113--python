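import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from codesel.case_study import (
    delong_test,
    depth_and_importance_comparison,
    fit_outcome_model,
    mcnemar_test,
    predict_scores,
    roc_auc_mannwhitney,
    run_case_study,
    shapley_contributions,
    shapley_importance,
    upsample_minority,
)
from codesel.hierarchy import build_icd_hierarchy
from codesel.records import RecordMatrix

import oracles

SMALL_GRID = {"max_depth": [3], "learning_rate": [0.1],
              "n_estimators": [50], "min_child_weight": [1]}


def toy_matrix(rng, n=200, d=8, signal_col=0):
    x = (rng.random((n, d)) < 0.3).astype(np.uint8)
    y = x[:, signal_col].astype(np.uint8)
    meta = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                         "window_index": np.zeros(n, dtype=int)})
    return RecordMatrix(values=x, feature_codes=[f"c{j}" for j in range(d)],
                        record_meta=meta, outcome=y)


class TestUpsampling:
    def test_balances_exactly(self, rng):
        m = toy_matrix(rng)
        m.outcome = (rng.random(200) < 0.1).astype(np.uint8)
        bal = upsample_minority(m, seed=0)
        counts = np.bincount(bal.outcome)
        assert counts[0] == counts[1]

    def test_already_balanced_untouched(self, rng):
        m = toy_matrix(rng, n=20)
        m.outcome = np.repeat([0, 1], 10).astype(np.uint8)
        bal = upsample_minority(m, seed=0)
        assert bal.n_records == 20

    def test_resampled_rows_are_copies(self, rng):
        m = toy_matrix(rng, n=50)
        m.outcome = np.array([1] * 5 + [0] * 45, dtype=np.uint8)
        bal = upsample_minority(m, seed=1)
        originals = {tuple(r) for r in m.values[m.outcome == 1]}
        added = bal.values[50:]
        assert all(tuple(r) in originals for r in added)

    def test_single_class_rejected(self, rng):
        m = toy_matrix(rng, n=20)
        m.outcome = np.zeros(20, dtype=np.uint8)
        with pytest.raises(ValueError):
            upsample_minority(m, seed=0)


class TestOutcomeModel:
    def test_separable_outcome_reaches_perfect_auc(self, rng):
        m = toy_matrix(rng)
        model = fit_outcome_model(m, np.arange(8), seed=0, grid=SMALL_GRID)
        assert roc_auc_mannwhitney(predict_scores(model, m), m.outcome) == 1.0

    def test_permuted_labels_give_null_auc(self):
        """Outcome independent of all features: held-out AUC near 1/2."""
        rng = np.random.default_rng(0)
        n = 2000
        x = (rng.random((n, 10)) < 0.3).astype(np.uint8)
        y = (rng.random(n) < 0.2).astype(np.uint8)
        meta = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                             "window_index": np.zeros(n, dtype=int)})
        m = RecordMatrix(values=x, feature_codes=[f"c{j}" for j in range(10)],
                         record_meta=meta, outcome=y)
        train = m.take_rows(np.arange(0, 1400))
        test = m.take_rows(np.arange(1400, n))
        model = fit_outcome_model(train, np.arange(10), seed=0, grid=SMALL_GRID)
        auc = roc_auc_mannwhitney(predict_scores(model, test), test.outcome)
        assert 0.4 <= auc <= 0.6

    def test_deterministic_given_seed(self, rng):
        m = toy_matrix(rng)
        s1 = predict_scores(fit_outcome_model(m, np.arange(8), 3, grid=SMALL_GRID), m)
        s2 = predict_scores(fit_outcome_model(m, np.arange(8), 3, grid=SMALL_GRID), m)
        assert np.array_equal(s1, s2)


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        auc_a, auc_b, p = delong_test(s, s.copy(), y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_auc_matches_mannwhitney_and_sklearn(self, rng):
        s1, s2 = rng.random(150), rng.random(150)
        y = (rng.random(150) < 0.4).astype(int)
        auc_a, auc_b, _ = delong_test(s1, s2, y)
        assert np.isclose(auc_a, roc_auc_score(y, s1), atol=1e-10)
        assert np.isclose(auc_a, oracles.auc_by_pair_counting(s1, y), atol=1e-10)
        assert np.isclose(auc_b, roc_auc_score(y, s2), atol=1e-10)

    def test_symmetric_in_arguments(self, rng):
        s1, s2 = rng.random(80), rng.random(80)
        y = (rng.random(80) < 0.5).astype(int)
        a1, b1, p1 = delong_test(s1, s2, y)
        a2, b2, p2 = delong_test(s2, s1, y)
        assert (a1, b1) == (b2, a2)
        assert np.isclose(p1, p2, atol=1e-12)

    def test_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(42)
        y = (rng.random(200) < 0.35).astype(int)
        s1 = y * 0.4 + rng.random(200)
        s2 = y * 0.2 + rng.random(200)
        _, _, p = delong_test(s1, s2, y)
        p_boot = oracles.bootstrap_delong_p(s1, s2, y, n_boot=10_000, seed=1)
        assert abs(p - p_boot) < 0.02

    def test_constant_scores_rejected(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(ValueError, match="constant"):
            delong_test(np.ones(50), rng.random(50), y)


class TestMcNemar:
    def test_identical_predictions_give_p_one(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        pred = (rng.random(40) < 0.5).astype(int)
        p, degenerate = mcnemar_test(pred, pred.copy(), y)
        assert p == 1.0 and degenerate

    def test_exact_binomial_closed_form(self):
        """b=15, c=0 discordant pairs: p = 2 * 0.5^15."""
        y = np.zeros(30, dtype=int)
        pred_a = np.zeros(30, dtype=int)
        pred_b = np.concatenate([np.ones(15, dtype=int), np.zeros(15, dtype=int)])
        p, _ = mcnemar_test(pred_a, pred_b, y)
        assert np.isclose(p, 2 * 0.5 ** 15, rtol=1e-10)

    def test_chi_square_with_continuity_correction(self):
        """b=40, c=20: statistic (|40-20|-1)^2/60, p ~ 0.0142."""
        n = 70
        y = np.zeros(n, dtype=int)
        pred_a = np.concatenate([np.zeros(40, int), np.ones(20, int), np.zeros(10, int)])
        pred_b = np.concatenate([np.ones(40, int), np.zeros(30, int)])
        p, _ = mcnemar_test(pred_a, pred_b, y)
        from scipy.stats import chi2
        assert np.isclose(p, chi2.sf((abs(40 - 20) - 1) ** 2 / 60, 1), rtol=1e-12)
        assert np.isclose(p, 0.0142, atol=5e-4)


class TestShapley:
    def test_additivity_to_margin(self, rng):
        m = toy_matrix(rng)
        model = fit_outcome_model(m, np.arange(8), seed=0, grid=SMALL_GRID)
        contribs = shapley_contributions(model, m)
        import xgboost as xgb
        margin = model.get_booster().predict(
            xgb.DMatrix(m.values[:, np.arange(8)].astype(float)), output_margin=True)
        assert np.abs(contribs.sum(axis=1) - margin).max() < 1e-5

    def test_unused_features_get_zero(self, rng):
        m = toy_matrix(rng)
        # outcome is exactly feature 0; depth-1 stumps only need feature 0
        model = fit_outcome_model(m, np.arange(8), seed=0,
                                  grid={"max_depth": [1], "learning_rate": [0.3],
                                        "n_estimators": [20], "min_child_weight": [1]})
        shap = shapley_importance(model, m)
        assert np.argmax(shap) == 0
        assert shap[1:].max() <= 1e-8


class TestDepthComparison:
    def test_root_only_selection_has_depth_zero(self):
        hier = build_icd_hierarchy([("A", None, ""), ("B", "A", ""), ("C", None, "")])
        codes = ["A", "B", "C"]
        table = depth_and_importance_comparison(
            {"m1": np.array([0, 2, 0]), "caeww": np.array([1, 1, 1])},
            codes, hier, reference="caeww")
        assert table.loc["m1", "mean_depth"] == 0.0

    def test_identical_selections_give_p_one(self):
        hier = build_icd_hierarchy([("A", None, ""), ("B", "A", ""), ("C", "B", "")])
        codes = ["A", "B", "C"]
        sel = np.array([0, 1, 2])
        table = depth_and_importance_comparison(
            {"m1": sel, "caeww": sel.copy()}, codes, hier, reference="caeww")
        assert np.isclose(table.loc["m1", "depth_p_vs_reference"], 1.0)

    def test_welch_matches_textbook_oracle(self):
        rows = [(f"N{i}", f"N{i-1}" if i else None, "") for i in range(5)]
        hier = build_icd_hierarchy(rows)
        codes = [f"N{i}" for i in range(5)]
        table = depth_and_importance_comparison(
            {"m1": np.array([0, 1, 2]), "caeww": np.array([2, 3, 4])},
            codes, hier, reference="caeww")
        _, p = oracles.welch_t_p(np.array([0.0, 1.0, 2.0]), np.array([2.0, 3.0, 4.0]))
        assert np.isclose(table.loc["m1", "depth_p_vs_reference"], p, atol=1e-10)


def test_run_case_study_end_to_end(rng):
    m = toy_matrix(rng, n=300)
    m.outcome = ((m.values[:, 0] == 1) | (rng.random(300) < 0.05)).astype(np.uint8)
    train = m.take_rows(np.arange(200))
    test = m.take_rows(np.arange(200, 300))
    hier = build_icd_hierarchy([(f"c{j}", None, "") for j in range(8)])
    report, scores, preds = run_case_study(
        train, test, np.arange(8), seed=0, grid=SMALL_GRID,
        feature_codes=m.feature_codes, hierarchy=hier)
    assert 0.9 <= report.auc_roc <= 1.0
    assert report.mean_selected_depth == 0.0
    assert report.shap_mean_abs.shape == (8,)
    # compare a second run against the first as reference
    report2, _, _ = run_case_study(
        train, test, np.arange(8), seed=0, grid=SMALL_GRID,
        reference_scores=scores, reference_preds=preds,
        feature_codes=m.feature_codes, hierarchy=hier)
    assert report2.delong_p_vs_reference == 1.0
    assert report2.mcnemar_p_vs_reference == 1.0
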
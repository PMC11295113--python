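"""Supervised validation of selected features on a rare binary outcome.

Mirrors a mortality-style case study: the minority class of the training
split is upsampled to balance, a gradient-boosted tree classifier
(XGBoost) is tuned by seeded stratified cross-validation over a small
documented grid, and the tuned model is interrogated on the held-out
split with threshold metrics, AUC, exact tree Shapley attributions, and
paired statistical comparisons between methods (DeLong for correlated
AUCs, McNemar for thresholded predictions, Welch t-tests for the depth
and importance profiles of the selected codes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .hierarchy import CodeHierarchy

#: hyperparameter grid searched by ``fit_outcome_model`` (documented, fixed)
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [100, 300],
    "min_child_weight": [1, 5],
}


@dataclass
class CaseStudyReport:
    accuracy: float
    f1: float
    auc_roc: float
    delong_p_vs_reference: float | None
    mcnemar_p_vs_reference: float | None
    shap_mean_abs: np.ndarray
    mean_selected_depth: float
    best_params: dict = field(default_factory=dict)


def upsample_minority(matrix, seed: int):
    """Resample the minority class with replacement until classes balance.

    Majority rows are untouched; every added row is an exact copy of an
    original minority row.
    """
    if matrix.outcome is None:
        raise ValueError("matrix has no outcome labels")
    y = np.asarray(matrix.outcome).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return matrix
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return matrix.take_rows(idx)


def fit_outcome_model(balanced_matrix, selected, seed: int, cv_folds: int = 5,
                      grid: dict[str, list] | None = None) -> xgb.XGBClassifier:
    """Tune and fit a gradient-boosted tree classifier on selected columns.

    Hyperparameters maximize mean ROC AUC over seeded stratified folds;
    ties keep the earliest grid point.  Folds shrink if a class has
    fewer members than ``cv_folds``.
    """
    grid = grid or DEFAULT_GRID
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected feature set is empty")
    x = np.asarray(balanced_matrix.values, dtype=float)[:, selected]
    y = np.asarray(balanced_matrix.outcome).astype(int)
    min_class = int(np.bincount(y).min())
    if min_class < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 members")
    folds = min(cv_folds, min_class)

    names = list(grid)
    combos = list(itertools.product(*(grid[k] for k in names)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))

    best_auc, best_params = -np.inf, dict(zip(names, combos[0]))
    for combo in combos:
        params = dict(zip(names, combo))
        aucs = []
        for tr, va in splits:
            clf = _make_xgb(params, seed)
            clf.fit(x[tr], y[tr])
            aucs.append(roc_auc_score(y[va], clf.predict_proba(x[va])[:, 1]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:            # strict: ties keep earliest combo
            best_auc, best_params = mean_auc, params

    model = _make_xgb(best_params, seed)
    model.fit(x, y)
    model.codesel_selected_ = selected
    model.codesel_best_params_ = best_params
    model.codesel_cv_auc_ = best_auc
    return model


def _make_xgb(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


def predict_scores(model: xgb.XGBClassifier, matrix) -> np.ndarray:
    x = np.asarray(matrix.values, dtype=float)[:, model.codesel_selected_]
    return model.predict_proba(x)[:, 1]


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_mannwhitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    ranks = _midrank(np.concatenate([pos, neg]))
    m, n = len(pos), len(neg)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """Two-sided comparison of two correlated AUCs on the same test rows.

    Uses placement values (structural components): for each classifier
    the per-positive and per-negative placements estimate the AUC, and
    their empirical covariance across the shared rows gives the variance
    of the AUC difference; the p-value is normal.  Returns
    ``(auc_a, auc_b, p)``.
    """
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    placements, aucs = [], []
    for s in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        if np.ptp(s) == 0:
            raise ValueError("constant score vector: ROC undefined")
        pos, neg = s[labels == 1], s[labels == 0]
        m, n = len(pos), len(neg)
        all_ranks = _midrank(np.concatenate([pos, neg]))
        pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
        v_pos = (all_ranks[:m] - pos_ranks) / n          # placement of positives
        v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # placement of negatives
        aucs.append(float(v_pos.mean()))
        placements.append((v_pos, v_neg))

    m, n = len(placements[0][0]), len(placements[0][1])
    s10 = np.cov(np.vstack([placements[0][0], placements[1][0]]))
    s01 = np.cov(np.vstack([placements[0][1], placements[1][1]]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return aucs[0], aucs[1], p


def mcnemar_test(pred_a: np.ndarray, pred_b: np.ndarray,
                 labels: np.ndarray) -> tuple[float, bool]:
    """Paired comparison of two classifiers from discordant counts.

    ``b`` counts rows where A is right and B wrong, ``c`` the reverse.
    Exact two-sided binomial test when ``b + c < 25``, otherwise the
    chi-square statistic with continuity correction
    ``(|b - c| - 1)^2 / (b + c)``.  Returns ``(p, degenerate)`` where
    ``degenerate`` flags ``b + c == 0`` (p is then 1).
    """
    pred_a, pred_b = np.asarray(pred_a).astype(int), np.asarray(pred_b).astype(int)
    labels = np.asarray(labels).astype(int)
    right_a, right_b = pred_a == labels, pred_b == labels
    b = int((right_a & ~right_b).sum())
    c = int((~right_a & right_b).sum())
    if b + c == 0:
        return 1.0, True
    if b + c < 25:
        p = stats.binomtest(b, b + c, 0.5).pvalue
    else:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        p = stats.chi2.sf(chi2, df=1)
    return float(min(p, 1.0)), False


def shapley_importance(model: xgb.XGBClassifier, matrix) -> np.ndarray:
    """Mean absolute exact tree-Shapley attribution per selected feature.

    Attributions are computed on the margin scale via the booster's
    exact tree-path algorithm; per row they sum (with the bias term) to
    the model's margin output.
    """
    x = np.asarray(matrix.values, dtype=float)[:, model.codesel_selected_]
    if x.shape[1] != model.get_booster().num_features():
        raise ValueError("feature count mismatch between model and matrix")
    contribs = model.get_booster().predict(xgb.DMatrix(x), pred_contribs=True)
    return np.abs(contribs[:, :-1]).mean(axis=0)


def shapley_contributions(model: xgb.XGBClassifier, matrix) -> np.ndarray:
    """Raw per-row attributions (last column = bias), margin scale."""
    x = np.asarray(matrix.values, dtype=float)[:, model.codesel_selected_]
    return model.get_booster().predict(xgb.DMatrix(x), pred_contribs=True)


def run_case_study(train_matrix, test_matrix, selected, seed: int,
                   cv_folds: int = 5, grid: dict | None = None,
                   reference_scores: np.ndarray | None = None,
                   reference_preds: np.ndarray | None = None,
                   feature_codes: list[str] | None = None,
                   hierarchy: CodeHierarchy | None = None,
                   threshold: float = 0.5) -> tuple[CaseStudyReport, np.ndarray, np.ndarray]:
    """Full supervised track for one selection.

    Returns ``(report, test_scores, test_predictions)`` so that a later
    method's run can be compared against this one as the reference.
    """
    balanced = upsample_minority(train_matrix, seed)
    model = fit_outcome_model(balanced, selected, seed, cv_folds=cv_folds, grid=grid)
    scores = predict_scores(model, test_matrix)
    preds = (scores > threshold).astype(int)
    y = np.asarray(test_matrix.outcome).astype(int)

    auc = roc_auc_mannwhitney(scores, y)
    acc = float((preds == y).mean())
    f1 = float(f1_score(y, preds, zero_division=0.0))
    shap_vec = shapley_importance(model, test_matrix)

    delong_p = mcnemar_p = None
    if reference_scores is not None:
        _, _, delong_p = delong_test(scores, reference_scores, y)
    if reference_preds is not None:
        mcnemar_p, _ = mcnemar_test(preds, reference_preds, y)

    mean_depth = float("nan")
    if feature_codes is not None and hierarchy is not None:
        depths = [hierarchy.depth(feature_codes[j]) for j in np.asarray(selected)]
        mean_depth = float(np.mean(depths))

    report = CaseStudyReport(
        accuracy=acc, f1=f1, auc_roc=auc,
        delong_p_vs_reference=delong_p, mcnemar_p_vs_reference=mcnemar_p,
        shap_mean_abs=shap_vec, mean_selected_depth=mean_depth,
        best_params=model.codesel_best_params_,
    )
    return report, scores, preds


def depth_and_importance_comparison(
    selections: dict[str, np.ndarray],
    feature_codes: list[str],
    hierarchy: CodeHierarchy,
    shap_values: dict[str, np.ndarray] | None = None,
    reference: str = "caeww",
) -> pd.DataFrame:
    """Per-method depth (and optional importance) profile of the selected
    codes, with pairwise two-sided Welch t-tests against a reference.

    Methods with fewer than 3 selected features are excluded with a
    warning column rather than an error.
    """
    if len(selections) < 2:
        raise ValueError("need at least two methods to compare")
    if reference not in selections:
        raise ValueError(f"reference method {reference!r} not among selections")

    depths = {
        m: np.array([hierarchy.depth(feature_codes[j]) for j in np.asarray(sel)], dtype=float)
        for m, sel in selections.items()
    }
    usable = {m for m, d in depths.items() if d.size >= 3}
    rows = []
    ref_d = depths[reference]
    for m, d in depths.items():
        row: dict = {"method": m, "n_selected": int(d.size),
                     "mean_depth": float(d.mean()) if d.size else float("nan")}
        if m == reference or m not in usable or reference not in usable:
            row["depth_p_vs_reference"] = float("nan")
        else:
            row["depth_p_vs_reference"] = float(
                stats.ttest_ind(d, ref_d, equal_var=False).pvalue)
        if shap_values is not None and m in shap_values:
            sv = np.asarray(shap_values[m], dtype=float)
            row["mean_abs_shap"] = float(sv.mean())
            if m != reference and reference in shap_values and sv.size >= 3:
                row["shap_p_vs_reference"] = float(
                    stats.ttest_ind(sv, np.asarray(shap_values[reference], float),
                                    equal_var=False).pvalue)
            else:
                row["shap_p_vs_reference"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
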
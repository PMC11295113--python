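"""Independent brute-force oracles used only by the test suite.

Everything here is written as plainly as possible — explicit loops,
enumeration, closed forms, resampling — and never calls into the code
paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- Laplacian

def dense_laplacian_scores(x: np.ndarray, k: int) -> np.ndarray:
    """Laplacian score per feature via explicit dense loops.

    Neighbour tie rule: among equidistant samples the lowest index wins
    (the documented graph contract).
    """
    n, d = x.shape
    w = np.zeros((n, n))
    for i in range(n):
        dist = [(float(np.sum((x[i] - x[j]) ** 2)), j) for j in range(n) if j != i]
        dist.sort()
        for _, j in dist[:k]:
            w[i, j] = 1.0
    w = np.maximum(w, w.T)
    deg = w.sum(axis=1)
    lap = np.diag(deg) - w
    ones = np.ones(n)
    scores = np.empty(d)
    for f in range(d):
        col = x[:, f].astype(float)
        centered = col - (col @ (deg * ones)) / (ones @ (deg * ones)) * ones
        den = centered @ (deg * centered)
        scores[f] = np.inf if den <= 1e-12 else (centered @ (lap @ centered)) / den
    return scores


# ------------------------------------------------------------------- lasso

def lasso_by_active_set_enumeration(x: np.ndarray, y: np.ndarray, alpha: float,
                                    max_active: int) -> np.ndarray:
    """Exact lasso solution by enumerating active sets and sign patterns.

    Solves ``min (1/2n)||y - Xw||^2 + alpha ||w||_1`` by checking the
    KKT conditions of every (active set, sign vector) combination up to
    ``max_active`` features.  Singular active sets are skipped (with
    exactly duplicated columns the minimal-support solution is still
    found).  Returns the first KKT-consistent solution.
    """
    n, d = x.shape
    lam = alpha * n          # rescale to min 1/2||y-Xw||^2 + lam ||w||_1
    tol = 1e-8
    for size in range(0, max_active + 1):
        for active in itertools.combinations(range(d), size):
            xa = x[:, active]
            gram = xa.T @ xa
            if size and abs(np.linalg.det(gram)) < 1e-12:
                continue
            for signs in itertools.product((1.0, -1.0), repeat=size):
                s = np.asarray(signs)
                if size:
                    wa = np.linalg.solve(gram, xa.T @ y - lam * s)
                    if np.any(np.sign(wa) != s):
                        continue
                else:
                    wa = np.zeros(0)
                r = y - (xa @ wa if size else 0.0)
                corr = x.T @ r
                ok = True
                for j in range(d):
                    if j in active:
                        continue
                    if abs(corr[j]) > lam + 1e-6:
                        ok = False
                        break
                if ok:
                    w = np.zeros(d)
                    for pos, j in enumerate(active):
                        w[j] = wa[pos]
                    return w
    raise RuntimeError("no KKT-consistent lasso solution found")


# ------------------------------------------------------------------ t-test

def welch_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.special import stdtr
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, p


def paired_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test from the textbook formulas."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    n = len(diff)
    t = diff.mean() / (diff.std(ddof=1) / math.sqrt(n))
    from scipy.special import stdtr
    p = 2 * (1 - stdtr(n - 1, abs(t)))
    return t, p


# ------------------------------------------------------------------ DeLong

def auc_by_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by counting concordant positive/negative pairs (ties 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bootstrap_delong_p(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray, n_boot: int = 10_000,
                       seed: int = 0) -> float:
    """Two-sided p for the AUC difference via paired row bootstrap.

    The observed difference is divided by the bootstrap standard error
    of the difference and referred to a normal.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels).astype(int)
    n = len(labels)

    def fast_auc(s, y):
        pos, neg = s[y == 1], s[y == 0]
        from scipy.stats import rankdata
        r = rankdata(np.concatenate([pos, neg]))
        m = len(pos)
        return (r[:m].sum() - m * (m + 1) / 2) / (m * len(neg))

    observed = fast_auc(scores_a, labels) - fast_auc(scores_b, labels)
    diffs = []
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, size=n)
        y = labels[idx]
        if y.min() == y.max():
            continue
        diffs.append(fast_auc(scores_a[idx], y) - fast_auc(scores_b[idx], y))
    se = np.std(diffs, ddof=1)
    if se == 0:
        return 1.0
    from scipy.stats import norm
    return float(2 * norm.sf(abs(observed) / se))
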
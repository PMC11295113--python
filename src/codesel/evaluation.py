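"""Reconstruction-based evaluation of a selected feature set.

A selection is scored by how well the selected columns alone predict the
full one-hot feature space: a small feed-forward decoder (two hidden
layers of 64 leaky-ReLU units with 10% dropout, sigmoid outputs, binary
cross-entropy) is trained on the train split and evaluated per feature
on the test split.  Because sparse code matrices make raw accuracy look
uniformly high, every comparison is anchored against a mode baseline
that outputs each feature's training-set majority value regardless of
input, and a two-tailed t-test across features decides whether the
method beats that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._nn import MLP, Adam, bce, minibatches


@dataclass
class ReconstructorConfig:
    hidden: list[int] = field(default_factory=lambda: [64, 64])
    dropout: float = 0.1
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 10          # early stop after this many non-improving epochs
    min_delta: float = 1e-5


@dataclass
class ReconstructionReport:
    """Per-feature reconstruction accuracy/BCE against the mode baseline."""

    per_feature_accuracy: np.ndarray
    mean_accuracy: float
    mean_bce: float
    baseline_per_feature_accuracy: np.ndarray
    baseline_mean_accuracy: float
    baseline_mean_bce: float
    t_statistic: float
    t_test_p: float
    degenerate_variance: bool = False


class Reconstructor:
    """Handle around a trained reconstruction net."""

    def __init__(self, net: MLP, selected: np.ndarray, train_losses: list[float]):
        self.net = net
        self.selected = np.asarray(selected, dtype=int)
        self.train_losses = train_losses

    def predict(self, matrix) -> np.ndarray:
        x = np.asarray(matrix.values if hasattr(matrix, "values") else matrix, dtype=float)
        return self.net.predict(x[:, self.selected])


def train_reconstructor(train_matrix, selected, seed: int,
                        config: ReconstructorConfig | None = None) -> Reconstructor:
    """Train the selected-columns -> all-columns decoder.

    Deterministic given ``seed``; training stops early once the epoch
    loss has not improved by ``min_delta`` for ``patience`` epochs.
    """
    config = config or ReconstructorConfig()
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected feature set is empty")
    x = np.asarray(train_matrix.values if hasattr(train_matrix, "values") else train_matrix,
                   dtype=float)
    n, d = x.shape
    xin = x[:, selected]
    rng = np.random.default_rng(seed)
    net = MLP([selected.size, *config.hidden, d], rng, out_activation="sigmoid")
    opt = Adam(net.params, lr=config.learning_rate)

    best = np.inf
    stale = 0
    losses: list[float] = []
    for epoch in range(config.epochs):
        batch_losses = []
        for idx in minibatches(n, config.batch_size, rng):
            out, cache = net.forward(xin[idx], dropout=config.dropout, rng=rng)
            loss = bce(out, x[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
            batch_losses.append(loss)
            p = np.clip(out, 1e-7, 1 - 1e-7)
            dpre = (p - x[idx]) / p.size
            grads, _ = net.backward(cache, dpre)
            opt.step(grads)
        epoch_loss = float(np.mean(batch_losses))
        losses.append(epoch_loss)
        if epoch_loss < best - config.min_delta:
            best, stale = epoch_loss, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return Reconstructor(net, selected, losses)


def mode_baseline(train_matrix) -> np.ndarray:
    """Per-feature training-set majority value; exact 50/50 ties break to
    0 (absence, the majority regime in sparse code data)."""
    x = np.asarray(train_matrix.values if hasattr(train_matrix, "values") else train_matrix)
    if x.shape[0] == 0:
        raise ValueError("empty training matrix")
    return (x.mean(axis=0) > 0.5).astype(np.uint8)


def baseline_probabilities(train_matrix, eps: float = 1e-7) -> np.ndarray:
    """Clipped per-feature training frequencies, used as the baseline's
    predicted probabilities when computing its cross-entropy."""
    x = np.asarray(train_matrix.values if hasattr(train_matrix, "values") else train_matrix)
    return np.clip(x.mean(axis=0), eps, 1 - eps)


def per_feature_accuracy(pred_prob: np.ndarray, target: np.ndarray,
                         threshold: float = 0.5) -> np.ndarray:
    return ((pred_prob > threshold) == (target > 0.5)).mean(axis=0)


def per_feature_bce(pred_prob: np.ndarray, target: np.ndarray) -> np.ndarray:
    p = np.clip(pred_prob, 1e-7, 1 - 1e-7)
    return (-(target * np.log(p) + (1 - target) * np.log(1 - p))).mean(axis=0)


def compare_to_baseline(method_accuracy: np.ndarray, baseline_accuracy: np.ndarray,
                        method_bce: np.ndarray, baseline_bce: np.ndarray,
                        paired: bool = True) -> ReconstructionReport:
    """Two-sided t-test of method vs baseline accuracies across features.

    Paired by default (both are evaluated feature-by-feature on the same
    columns); ``paired=False`` gives the Welch variant.  A zero-variance
    difference vector is degenerate: p is reported as 0 (all differences
    equal and nonzero) or 1 (all zero), with a flag.
    """
    method_accuracy = np.asarray(method_accuracy, dtype=float)
    baseline_accuracy = np.asarray(baseline_accuracy, dtype=float)
    if method_accuracy.shape != baseline_accuracy.shape:
        raise ValueError("accuracy vectors must be aligned")
    if method_accuracy.size < 3:
        raise ValueError("t-test undefined with fewer than 3 features")

    degenerate = False
    if paired:
        diffs = method_accuracy - baseline_accuracy
        if np.allclose(diffs.std(), 0.0):
            degenerate = True
            t_stat = 0.0 if np.allclose(diffs, 0.0) else np.inf * np.sign(diffs.mean())
            p_val = 1.0 if np.allclose(diffs, 0.0) else np.finfo(float).tiny
        else:
            t_stat, p_val = stats.ttest_rel(method_accuracy, baseline_accuracy)
    else:
        t_stat, p_val = stats.ttest_ind(method_accuracy, baseline_accuracy, equal_var=False)
        if np.isnan(p_val):
            degenerate, t_stat, p_val = True, 0.0, 1.0

    return ReconstructionReport(
        per_feature_accuracy=method_accuracy,
        mean_accuracy=float(method_accuracy.mean()),
        mean_bce=float(np.mean(method_bce)),
        baseline_per_feature_accuracy=baseline_accuracy,
        baseline_mean_accuracy=float(baseline_accuracy.mean()),
        baseline_mean_bce=float(np.mean(baseline_bce)),
        t_statistic=float(t_stat),
        t_test_p=float(p_val),
        degenerate_variance=degenerate,
    )


def evaluate_selection(train_matrix, test_matrix, selected, seed: int,
                       config: ReconstructorConfig | None = None) -> ReconstructionReport:
    """End-to-end reconstruction evaluation of one selected feature set."""
    model = train_reconstructor(train_matrix, selected, seed, config)
    x_test = np.asarray(test_matrix.values if hasattr(test_matrix, "values") else test_matrix,
                        dtype=float)
    pred = model.predict(test_matrix)
    acc = per_feature_accuracy(pred, x_test)
    bce_vec = per_feature_bce(pred, x_test)

    mode = mode_baseline(train_matrix).astype(float)
    base_prob = baseline_probabilities(train_matrix)
    base_acc = (x_test == mode[None, :]).mean(axis=0)
    base_bce = per_feature_bce(np.broadcast_to(base_prob, x_test.shape), x_test)
    return compare_to_baseline(acc, base_acc, bce_vec, base_bce)
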
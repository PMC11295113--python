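"""Unsupervised feature selection for sparse binary code matrices.

Five method families behind one result type:

* **Laplacian score (LS)** — a filter statistic from a k-nearest-neighbour
  sample graph; features that vary little across neighbouring samples
  relative to their overall variance score low, and low is good.
* **MCFS** — multi-cluster feature selection: graph-Laplacian eigenvectors
  are regressed on the feature columns with an L1 (LARS) penalty and each
  feature is scored by its largest absolute coefficient.
* **AEFS** — a single-hidden-layer autoencoder with a group-sparsity
  (row-wise L2-then-sum) penalty on the first-layer weights; features are
  ranked by the norm of their weight row.
* **PFA** — principal feature analysis: k-means on the PCA loading rows,
  keeping per cluster the feature closest to the centroid.
* **CAE** — the concrete autoencoder: an encoder of ``n_best`` selector
  neurons, each holding a logit vector over all features, sampled with
  Gumbel-Softmax at an exponentially annealed temperature and decoded by
  a small feed-forward net under binary cross-entropy.  An optional
  per-feature loss weighting of ``1/(1+depth)`` steers selection toward
  codes near the top of the hierarchy (the weighted variant is usually
  called CAEWW, the plain one CAENW).

All graph constructions are over SAMPLES, following the original LS/MCFS
formulations.  Selection everywhere breaks ties toward the lowest feature
index, and every method is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.cluster import KMeans
from sklearn.decomposition import IncrementalPCA
from sklearn.linear_model import lars_path

from ._nn import MLP, Adam, bce, minibatches, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult", "LSConfig", "MCFSConfig", "AEFSConfig", "PFAConfig",
    "CAEConfig", "laplacian_score", "mcfs_scores", "aefs_select",
    "pfa_select", "cae_select", "cae_temperature",
]


@dataclass
class SelectionResult:
    """Outcome of one selector run.

    ``scores`` is oriented so larger = more selected (it is ``None`` for
    PFA and CAE, which do not produce a total order over all features);
    ``selected`` holds unique feature indices, at most ``n_best`` of
    them; ``selector_assignment`` is CAE-only: the argmax feature of each
    selector neuron, duplicates allowed.
    """

    method: str
    selected: np.ndarray
    scores: np.ndarray | None = None
    selector_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        if self.selector_assignment is not None:
            assigned = np.unique(self.selector_assignment)
            if not np.array_equal(np.sort(self.selected), assigned):
                raise ValueError("selected must equal unique(selector_assignment)")


@dataclass
class LSConfig:
    k_neighbors: int = 5
    weight_mode: str = "binary"   # heat-kernel bandwidth t -> infinity


@dataclass
class MCFSConfig:
    k_neighbors: int = 5
    n_eigvecs: int = 5
    l1_budget: int | None = None  # cardinality cap of each LARS path; default n_best


@dataclass
class AEFSConfig:
    alpha: float = 0.001          # trade-off of the group-sparsity term
    beta: float = 0.1             # Frobenius weight decay
    hidden_units: int | None = None   # default ceil(n_features/2), capped at 256
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64


@dataclass
class PFAConfig:
    n_components: int | None = None   # default ceil(n_features/2)
    batch_size: int | None = None     # default 2 * n_features
    kmeans_retries: int = 5


@dataclass
class CAEConfig:
    temp_start: float = 20.0
    temp_end: float = 0.01
    epochs: int = 1000
    learning_rate: float = 1e-3
    batch_size: int = 64
    decoder_hidden: list[int] = field(default_factory=lambda: [64, 64])
    weight_adjust: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.temp_end < self.temp_start):
            raise ValueError("need 0 < temp_end < temp_start")


def _as_float(matrix) -> np.ndarray:
    values = matrix.values if hasattr(matrix, "values") else matrix
    return np.asarray(values, dtype=float)


def _top_k(scores: np.ndarray, k: int, largest: bool = True) -> np.ndarray:
    """Indices of the k best scores; ties go to the lowest index."""
    key = -scores if largest else scores
    order = np.lexsort((np.arange(len(scores)), key))
    return np.sort(order[:k])


def _knn_graph(x: np.ndarray, k: int):
    """Symmetric (union) binary k-NN adjacency over samples, plus the
    degree vector and the combinatorial Laplacian L = D - W.

    Binary code matrices produce many tied Euclidean distances, so the
    neighbour tie rule is part of the contract: among equidistant
    samples the lowest index wins.
    """
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n_samples={n}")
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))
        w[i, order[:k]] = 1.0
    w = np.maximum(w, w.T)
    deg = w.sum(axis=1)
    lap = np.diag(deg) - w
    return w, deg, lap


def laplacian_score(matrix, n_best: int, config: LSConfig | None = None) -> SelectionResult:
    """Laplacian-score filter selection.

    Builds the binary k-NN sample graph, removes each feature's
    degree-weighted mean, and scores it by the Rayleigh-style ratio
    ``(f'Lf)/(f'Df)``; the ``n_best`` features with the SMALLEST ratio
    are selected.  Constant features have a zero denominator and are
    assigned the worst possible score.  Reported ``scores`` are negated
    so the larger-is-better orientation holds across methods.
    """
    config = config or LSConfig()
    x = _as_float(matrix)
    _, deg, lap = _knn_graph(x, config.k_neighbors)
    deg_sum = deg.sum()
    centered = x - (deg @ x) / deg_sum          # f - (f'D1 / 1'D1) 1
    num = np.einsum("ij,ij->j", centered, lap @ centered)
    den = np.einsum("ij,ij->j", centered, deg[:, None] * centered)
    ls = np.full(x.shape[1], np.inf)
    ok = den > 1e-12
    ls[ok] = num[ok] / den[ok]
    if (~ok).any():
        logger.warning("%d constant feature(s) assigned worst Laplacian score",
                       int((~ok).sum()))
    selected = _top_k(ls, n_best, largest=False)
    return SelectionResult(method="ls", selected=selected, scores=-ls)


def _spectral_embedding(x: np.ndarray, k_neighbors: int, n_eigvecs: int) -> np.ndarray:
    """Smallest nontrivial generalized eigenvectors of L y = lambda D y."""
    _, deg, lap = _knn_graph(x, k_neighbors)
    try:
        vals, vecs = sla.eigh(lap, np.diag(deg))
    except sla.LinAlgError as exc:   # pragma: no cover - degenerate graphs
        raise RuntimeError(
            "eigen-solver failed on a degenerate neighbourhood graph; "
            "try a larger k_neighbors"
        ) from exc
    # drop the trivial constant eigenvector (eigenvalue ~0)
    return vecs[:, 1:1 + n_eigvecs]


def mcfs_scores(matrix, n_best: int, config: MCFSConfig | None = None) -> SelectionResult:
    """Multi-cluster feature selection.

    Each retained Laplacian eigenvector is regressed on the feature
    columns along a LARS lasso path capped at ``l1_budget`` active
    features; a feature's score is its maximum absolute coefficient
    across eigenvectors, and the ``n_best`` largest scores win.
    """
    config = config or MCFSConfig()
    x = _as_float(matrix)
    if config.n_eigvecs >= x.shape[0]:
        raise ValueError("n_eigvecs must be < n_samples")
    budget = config.l1_budget or n_best
    embedding = _spectral_embedding(x, config.k_neighbors, config.n_eigvecs)
    scores = np.zeros(x.shape[1])
    for j in range(embedding.shape[1]):
        coefs, _ = _lars_coefs_at_budget(x, embedding[:, j], budget)
        scores = np.maximum(scores, np.abs(coefs))
    selected = _top_k(scores, n_best, largest=True)
    return SelectionResult(method="mcfs", selected=selected, scores=scores)


def _lars_coefs_at_budget(x: np.ndarray, y: np.ndarray, budget: int
                          ) -> tuple[np.ndarray, float]:
    """Coefficients (and their regularization level) at the last
    lasso-LARS path point with <= budget active features.

    Both sides are mean-centered first (an implicit intercept), so an
    eigenvector supported on one graph component relates symmetrically
    to a binary feature and its complement.

    The returned alpha is on sklearn's scale: the path minimizes
    ``(1/2n)||y - Xw||^2 + alpha ||w||_1``.  Exactly duplicated columns
    make that solution non-unique; they are collapsed before the path
    (the whole group coefficient lands on the group's first member),
    which keeps the solution at the minimal-support extreme point.
    """
    x = x - x.mean(axis=0)
    y = y - y.mean()
    _, unique_idx = np.unique(x.T, axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    alphas, _, coefs_u = lars_path(x[:, unique_idx], y, method="lasso",
                                   max_iter=8 * budget)
    nnz = (coefs_u != 0).sum(axis=0)
    at_budget = np.flatnonzero(nnz >= budget)
    knot = at_budget[0] if at_budget.size else len(alphas) - 1
    coefs = np.zeros(x.shape[1])
    coefs[unique_idx] = coefs_u[:, knot]
    return coefs, float(alphas[knot])


def aefs_select(matrix, n_best: int, config: AEFSConfig | None = None,
                seed: int = 0) -> SelectionResult:
    """Autoencoder-inspired selection via group-sparse first-layer weights.

    Trains ``x -> leakyReLU(x W1 + b1) -> linear`` under squared
    reconstruction error plus ``alpha * sum_rows ||W1_row||_2`` (the
    group-sparsity penalty) and ``beta/2 * ||W||_F^2`` over all layers,
    then ranks features by the Euclidean norm of their W1 row.
    """
    config = config or AEFSConfig()
    x = _as_float(matrix)
    n, d = x.shape
    hidden = config.hidden_units or min(256, max(1, int(np.ceil(d / 2))))
    rng = np.random.default_rng(seed)
    # small symmetric init: weight-row norms are the selection scores, so
    # rows that never receive gradient must start (and stay) near zero
    net = MLP([d, hidden, d], rng, out_activation="linear", init_scale=0.01)
    opt = Adam(net.params, lr=config.learning_rate)
    for epoch in range(config.epochs):
        for idx in minibatches(n, config.batch_size, rng):
            xb = x[idx]
            out, cache = net.forward(xb)
            loss = 0.5 * np.mean((out - xb) ** 2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite AEFS loss at epoch {epoch}, lr={config.learning_rate}")
            dpre = (out - xb) / xb.size
            grads, _ = net.backward(cache, dpre)
            # group sparsity on W1 rows + Frobenius decay on all weights
            w1 = net.weights[0]
            row_norms = np.linalg.norm(w1, axis=1, keepdims=True)
            grads[0] += config.alpha * w1 / np.maximum(row_norms, 1e-12)
            for li, w in enumerate(net.weights):
                grads[2 * li] += config.beta * w
            opt.step(grads)
    scores = np.linalg.norm(net.weights[0], axis=1)
    selected = _top_k(scores, n_best, largest=True)
    return SelectionResult(method="aefs", selected=selected, scores=scores)


def pfa_select(matrix, n_best: int, config: PFAConfig | None = None,
               seed: int = 0) -> SelectionResult:
    """Principal feature analysis.

    Fits incremental PCA, represents each feature by its loading row
    across the retained components, clusters the rows into ``n_best``
    k-means clusters, and keeps per cluster the member feature closest
    (Euclidean) to the centroid, lowest index on ties.
    """
    config = config or PFAConfig()
    x = _as_float(matrix)
    n, d = x.shape
    if n_best > d:
        raise ValueError("n_best exceeds number of features")
    n_components = config.n_components or int(np.ceil(d / 2))
    n_components = min(n_components, n, d)
    batch = config.batch_size or 2 * d
    batch = max(batch, n_components)
    ipca = IncrementalPCA(n_components=n_components, batch_size=batch)
    ipca.fit(x)
    loadings = ipca.components_.T                  # (d, n_components)

    last_exc: Exception | None = None
    for attempt in range(config.kmeans_retries):
        km = KMeans(n_clusters=n_best, random_state=seed + attempt, n_init=10)
        labels = km.fit_predict(loadings)
        if len(np.unique(labels)) == n_best:
            break
        last_exc = RuntimeError(f"empty k-means cluster on attempt {attempt}")
    else:
        raise last_exc or RuntimeError("k-means failed")

    selected = []
    for c in range(n_best):
        members = np.flatnonzero(labels == c)
        dist = np.linalg.norm(loadings[members] - km.cluster_centers_[c], axis=1)
        selected.append(members[np.argmin(dist)])   # argmin ties -> lowest index
    return SelectionResult(method="pfa", selected=np.sort(np.asarray(selected)))


def cae_temperature(epoch: int, config: CAEConfig) -> float:
    """Exponential annealing schedule of the concrete-layer temperature:
    ``T(e) = T0 * (T1/T0)**(e/E)`` so T(0)=T0 and T(E)=T1."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    frac = epoch / config.epochs
    return float(config.temp_start * (config.temp_end / config.temp_start) ** frac)


def cae_select(matrix, n_best: int, config: CAEConfig | None = None,
               seed: int = 0, feature_weights: np.ndarray | None = None) -> SelectionResult:
    """Concrete-autoencoder selection, optionally with depth weighting.

    The encoder is a concrete selector layer of ``n_best`` neurons; each
    holds a logit vector over all features and outputs, during training,
    ``softmax((logits + Gumbel)/T(e)) @ x``.  The decoder is a leaky-ReLU
    feed-forward net with sigmoid outputs trained by binary cross-entropy
    over all original features; with ``weight_adjust`` each feature's BCE
    term is multiplied by its ``feature_weights`` entry (normalized by
    the weight sum).  After training each neuron commits to its argmax
    feature; duplicated choices collapse, so fewer than ``n_best``
    features may be returned.
    """
    config = config or CAEConfig()
    x = _as_float(matrix)
    n, d = x.shape
    if n_best > d:
        raise ValueError("n_best exceeds number of features")
    if config.weight_adjust:
        if feature_weights is None:
            raise ValueError("weight_adjust requires feature_weights")
        w_feat = np.asarray(feature_weights, dtype=float)
        if w_feat.shape != (d,) or (w_feat <= 0).any() or (w_feat > 1).any():
            raise ValueError("feature_weights must be per-feature values in (0, 1]")
    else:
        w_feat = np.ones(d)
    w_norm = w_feat / w_feat.sum()

    rng = np.random.default_rng(seed)
    logits = rng.normal(0.0, 0.01, size=(n_best, d))
    decoder = MLP([n_best, *config.decoder_hidden, d], rng, out_activation="sigmoid")
    opt = Adam([logits, *decoder.params], lr=config.learning_rate)

    epoch_losses = []
    for epoch in range(config.epochs):
        temp = cae_temperature(epoch, config)
        batch_losses = []
        for idx in minibatches(n, config.batch_size, rng):
            xb = x[idx]
            b = xb.shape[0]
            gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=(b, n_best, d))))
            a = (logits[None, :, :] + gumbel) / temp
            a -= a.max(axis=2, keepdims=True)
            s = np.exp(a)
            s /= s.sum(axis=2, keepdims=True)
            z = np.einsum("bkd,bd->bk", s, xb)

            out, cache = decoder.forward(z)
            loss = bce(out, xb, weights=w_feat)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite CAE loss at epoch {epoch}")
            batch_losses.append(loss)

            p = np.clip(out, 1e-7, 1 - 1e-7)
            dpre = (p - xb) * w_norm[None, :] / b
            grads, dz = decoder.backward(cache, dpre)
            ds = dz[:, :, None] * xb[:, None, :]
            da = (ds - (ds * s).sum(axis=2, keepdims=True)) * s / temp
            dlogits = da.sum(axis=0)
            opt.step([dlogits, *grads])
        epoch_losses.append(float(np.mean(batch_losses)))

    assignment = np.argmax(logits, axis=1)          # argmax ties -> lowest index
    selected = np.unique(assignment)
    result = SelectionResult(
        method="caeww" if config.weight_adjust else "cae",
        selected=selected,
        selector_assignment=assignment,
    )
    result.training_loss = epoch_losses             # monitoring, not part of the contract
    result.logits = logits
    return result
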
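import numpy as np
import pytest

from codesel.selectors import (
    AEFSConfig,
    CAEConfig,
    LSConfig,
    MCFSConfig,
    PFAConfig,
    SelectionResult,
    _lars_coefs_at_budget,
    aefs_select,
    cae_select,
    cae_temperature,
    laplacian_score,
    mcfs_scores,
    pfa_select,
)
from codesel.synthgen import planted_duplicates

import oracles


def random_binary(rng, n, d, p=0.3):
    return (rng.random((n, d)) < p).astype(float)


def two_blob_data(rng, n_per=20, d_noise=6):
    """Two well-separated sample clusters plus pure-noise features;
    feature 0 indicates the cluster perfectly."""
    cluster = np.repeat([0.0, 1.0], n_per)
    noise = (rng.random((2 * n_per, d_noise)) < 0.5).astype(float)
    x = np.column_stack([cluster, noise])
    # separate the blobs geometrically so the kNN graph splits them
    x = np.column_stack([x, np.repeat([0.0, 1.0], n_per), np.repeat([0.0, 1.0], n_per)])
    return x


class TestLaplacianScore:
    def test_matches_dense_oracle_on_random_matrices(self, rng):
        for trial in range(20):
            n = int(rng.integers(20, 41))
            d = int(rng.integers(6, 13))
            x = random_binary(rng, n, d)
            result = laplacian_score(x, n_best=d, config=LSConfig(k_neighbors=5))
            expected = oracles.dense_laplacian_scores(x, k=5)
            got = -result.scores
            finite = np.isfinite(expected)
            assert np.allclose(got[finite], expected[finite], atol=1e-8)
            assert np.array_equal(np.isfinite(got), finite)

    def test_duplicate_columns_score_identically(self, rng):
        x = random_binary(rng, 30, 6)
        x = np.column_stack([x, x[:, 2]])
        result = laplacian_score(x, n_best=3)
        assert result.scores[2] == result.scores[-1]

    def test_cluster_aligned_feature_beats_noise(self, rng):
        x = two_blob_data(rng)
        result = laplacian_score(x, n_best=1)
        ls = -result.scores
        assert ls[0] < min(ls[1:7])        # smaller score = more relevant

    def test_constant_feature_never_selected(self, rng):
        x = random_binary(rng, 30, 5)
        x[:, 3] = 1.0
        result = laplacian_score(x, n_best=4)
        assert 3 not in result.selected


class TestMCFS:
    def test_scores_match_active_set_oracle(self, rng):
        """Per duplicate-group max |coefficient| equals the exact lasso
        solution found by exhaustive KKT active-set enumeration."""
        from codesel.selectors import _spectral_embedding
        for trial in range(6):
            n = int(rng.integers(25, 41))
            d = int(rng.integers(6, 11))
            x = random_binary(rng, n, d)
            x = np.column_stack([x, x[:, 0]])       # plant a duplicate pair
            groups = list(range(d)) + [0]
            budget = 3
            embedding = _spectral_embedding(x, 5, 2)
            impl = np.zeros(d + 1)
            orac = np.zeros(d + 1)
            for j in range(embedding.shape[1]):
                y = embedding[:, j]
                coefs, alpha = _lars_coefs_at_budget(x, y, budget)
                # the regression is mean-centered on both sides
                xc, yc = x - x.mean(axis=0), y - y.mean()
                w = oracles.lasso_by_active_set_enumeration(xc, yc, alpha, budget)
                impl = np.maximum(impl, np.abs(coefs))
                orac = np.maximum(orac, np.abs(w))
            for g in set(groups):
                members = [i for i, gg in enumerate(groups) if gg == g]
                assert np.isclose(max(impl[m] for m in members),
                                  max(orac[m] for m in members), atol=1e-6)

    def test_separating_feature_ranks_first(self, rng):
        x = two_blob_data(rng)
        result = mcfs_scores(x, n_best=3, config=MCFSConfig(n_eigvecs=2))
        assert np.argmax(result.scores) == 0

    def test_deterministic(self, rng):
        x = random_binary(rng, 30, 8)
        r1 = mcfs_scores(x, 4, MCFSConfig(n_eigvecs=1))
        r2 = mcfs_scores(x, 4, MCFSConfig(n_eigvecs=1))
        assert np.array_equal(r1.selected, r2.selected)
        assert np.allclose(r1.scores, r2.scores)


class TestAEFS:
    def test_zero_column_ranks_behind_signal(self, rng):
        x = random_binary(rng, 20, 8, p=0.5)
        x[:, 5] = 0.0
        result = aefs_select(x, 3, AEFSConfig(alpha=0.0, beta=0.0, epochs=80), seed=0)
        assert result.scores[5] <= np.median(result.scores)
        assert 5 not in result.selected

    def test_generator_columns_recovered(self):
        """3 columns generate 9 attenuated linear mixtures; reconstructing
        from the generators needs the smallest weights, so the group
        penalty ranks them in the top 5."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            gen = (rng.random((100, 3)) < 0.5).astype(float)
            mix = np.zeros((9, 3))
            for j in range(9):
                pair = rng.choice(3, size=2, replace=False)
                mix[j, pair] = rng.uniform(0.25, 0.45, size=2)
            x = np.column_stack([gen, gen @ mix.T])
            result = aefs_select(x, 5, AEFSConfig(epochs=120), seed=seed)
            top5 = set(np.argsort(-result.scores)[:5])
            hits += len({0, 1, 2} & top5) >= 3
        assert hits >= 8

    def test_score_is_first_layer_row_norm(self, rng):
        x = random_binary(rng, 25, 6)
        result = aefs_select(x, 3, AEFSConfig(epochs=5), seed=1)
        assert result.scores.shape == (6,)
        assert (result.scores >= 0).all()

    def test_deterministic_given_seed(self, rng):
        x = random_binary(rng, 25, 6)
        r1 = aefs_select(x, 3, AEFSConfig(epochs=10), seed=3)
        r2 = aefs_select(x, 3, AEFSConfig(epochs=10), seed=3)
        assert np.array_equal(r1.selected, r2.selected)
        assert np.allclose(r1.scores, r2.scores)


class TestPFA:
    def test_every_feature_its_own_cluster(self, rng):
        x = random_binary(rng, 40, 6)
        result = pfa_select(x, n_best=6, seed=0)
        assert np.array_equal(result.selected, np.arange(6))

    def test_block_structure_covered(self):
        rng = np.random.default_rng(0)
        blocks = []
        for b in range(4):
            base = (rng.random(80) < 0.5).astype(float)
            for _ in range(3):
                blocks.append(base)
        x = np.column_stack(blocks)
        result = pfa_select(x, n_best=4, seed=0)
        covered = {j // 3 for j in result.selected}
        assert covered == {0, 1, 2, 3}

    def test_duplicates_share_cluster(self):
        rng = np.random.default_rng(1)
        x = (rng.random((50, 5)) < 0.4).astype(float)
        x = np.column_stack([x, x[:, 0]])
        from sklearn.cluster import KMeans
        from sklearn.decomposition import IncrementalPCA
        ipca = IncrementalPCA(n_components=3, batch_size=12).fit(x)
        loadings = ipca.components_.T
        labels = KMeans(n_clusters=3, random_state=0, n_init=10).fit_predict(loadings)
        assert labels[0] == labels[5]


class TestTemperatureSchedule:
    def test_endpoint_values(self):
        cfg = CAEConfig(epochs=1000)
        assert cae_temperature(0, cfg) == 20.0
        assert np.isclose(cae_temperature(1000, cfg), 0.01, atol=1e-12)

    def test_geometric_midpoint(self):
        cfg = CAEConfig(epochs=1000)
        assert np.isclose(cae_temperature(500, cfg), np.sqrt(20 * 0.01), atol=1e-12)

    def test_out_of_range_epoch_rejected(self):
        cfg = CAEConfig(epochs=100)
        with pytest.raises(ValueError):
            cae_temperature(101, cfg)
        with pytest.raises(ValueError):
            cae_temperature(-1, cfg)


class TestCAE:
    def test_selected_bounded_and_unique(self, rng):
        x = random_binary(rng, 60, 20)
        result = cae_select(x, 6, CAEConfig(epochs=30), seed=0)
        assert result.selected.size <= 6
        assert len(np.unique(result.selected)) == result.selected.size
        assert result.selector_assignment.shape == (6,)
        assert np.array_equal(np.sort(result.selected),
                              np.unique(result.selector_assignment))

    def test_deterministic_given_seed(self, rng):
        x = random_binary(rng, 50, 12)
        r1 = cae_select(x, 4, CAEConfig(epochs=25), seed=11)
        r2 = cae_select(x, 4, CAEConfig(epochs=25), seed=11)
        assert np.array_equal(r1.selector_assignment, r2.selector_assignment)
        assert np.allclose(r1.logits, r2.logits)

    def test_loss_decreases_over_training(self, rng):
        x = random_binary(rng, 100, 16)
        result = cae_select(x, 4, CAEConfig(epochs=60), seed=2)
        assert result.training_loss[-1] < result.training_loss[0]

    def test_unit_weights_equal_unweighted_run(self, rng):
        x = random_binary(rng, 50, 10)
        r_plain = cae_select(x, 3, CAEConfig(epochs=20), seed=5)
        r_unit = cae_select(x, 3, CAEConfig(epochs=20, weight_adjust=True),
                            seed=5, feature_weights=np.ones(10))
        assert np.array_equal(r_plain.selector_assignment, r_unit.selector_assignment)
        assert np.allclose(r_plain.logits, r_unit.logits)

    def test_generator_recovery_single_seed(self):
        x, groups = planted_duplicates(seed=0, n_samples=512)
        result = cae_select(x, 8, CAEConfig(epochs=200), seed=0)
        assert len(set(groups[result.selected])) >= 6

    def test_n_best_exceeding_features_rejected(self, rng):
        x = random_binary(rng, 20, 5)
        with pytest.raises(ValueError):
            cae_select(x, 6, CAEConfig(epochs=5), seed=0)

    def test_weight_values_validated(self, rng):
        x = random_binary(rng, 20, 5)
        with pytest.raises(ValueError):
            cae_select(x, 2, CAEConfig(epochs=5, weight_adjust=True), seed=0,
                       feature_weights=np.full(5, 1.5))


def test_selection_result_rejects_duplicates():
    with pytest.raises(ValueError):
        SelectionResult(method="x", selected=np.array([1, 1, 2]))


def test_all_selectors_obey_common_contract(rng):
    """Unique in-range indices, length <= n_best, reproducible."""
    x = random_binary(rng, 40, 12)
    runs = {
        "ls": lambda: laplacian_score(x, 5),
        "mcfs": lambda: mcfs_scores(x, 5, MCFSConfig(n_eigvecs=2)),
        "aefs": lambda: aefs_select(x, 5, AEFSConfig(epochs=10), seed=0),
        "pfa": lambda: pfa_select(x, 5, seed=0),
        "cae": lambda: cae_select(x, 5, CAEConfig(epochs=10), seed=0),
    }
    for name, run in runs.items():
        r1, r2 = run(), run()
        assert r1.selected.size <= 5, name
        assert np.all((0 <= r1.selected) & (r1.selected < 12)), name
        assert np.array_equal(r1.selected, r2.selected), name
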
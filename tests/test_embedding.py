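"""PCA component selection, t-SNE embedding, out-of-sample placement."""

from __future__ import annotations

import numpy as np
import pytest

from pfasmap.embed import (
    EmbeddingCoordinates,
    PCAModel,
    TSNEConfig,
    fit_pca,
    fit_tsne,
    place_user_points,
    transform_pca,
)


def _eigen_oracle(X: np.ndarray) -> np.ndarray:
    """Explained-variance ratios via brute-force covariance eigendecomposition."""
    center = X.mean(axis=0)
    std = X.std(axis=0)
    usable = std > 0
    Z = (X[:, usable] - center[usable]) / std[usable]
    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()


class TestPCA:
    def test_single_varying_column_needs_one_component(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        model, scores = fit_pca(X, variance_target=0.7)
        assert model.k == 1
        assert np.isclose(model.explained_variance_ratio.sum(), 1.0)
        assert scores.shape == (20, 1)

    def test_rank3_recovery_at_high_target(self, rng):
        factors = rng.normal(size=(60, 3))
        mixing = rng.normal(size=(3, 12))
        X = factors @ mixing + 1e-6 * rng.normal(size=(60, 12))
        model, _ = fit_pca(X, variance_target=0.99)
        assert model.k == 3

    @pytest.mark.parametrize("shape", [(10, 4), (30, 12), (50, 20)])
    def test_ratios_match_eigendecomposition_oracle(self, rng, shape):
        X = rng.normal(size=shape) * rng.uniform(0.5, 5.0, size=shape[1])
        model, _ = fit_pca(X, variance_target=1.0)
        oracle = _eigen_oracle(X)
        np.testing.assert_allclose(
            model.explained_variance_ratio, oracle[: model.k], atol=1e-8
        )

    def test_k_is_minimal_for_target(self, rng):
        X = rng.normal(size=(40, 15)) * np.linspace(5, 0.1, 15)
        full, _ = fit_pca(X, variance_target=1.0)
        cum = np.cumsum(_eigen_oracle(X))
        for target in (0.5, 0.7, 0.9, 0.99):
            model, _ = fit_pca(X, variance_target=target)
            assert model.k == int(np.searchsorted(cum, target - 1e-12) + 1)
            if model.k > 1:
                assert cum[model.k - 2] < target

    def test_raising_target_never_decreases_k(self, rng):
        X = rng.normal(size=(30, 10)) * np.linspace(3, 0.2, 10)
        ks = [fit_pca(X, t)[0].k for t in (0.3, 0.5, 0.7, 0.9, 0.999)]
        assert ks == sorted(ks)

    def test_loadings_orthonormal(self, bench_pca):
        model, _ = bench_pca
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.k), atol=1e-8)

    def test_transform_reproduces_fit_scores(self, rng):
        X = rng.normal(size=(25, 8))
        model, scores = fit_pca(X, variance_target=0.9)
        np.testing.assert_allclose(transform_pca(model, X), scores, atol=1e-8)

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(25, 8))
        model, _ = fit_pca(X, variance_target=0.9)
        scores = transform_pca(model, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_schema_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        model, _ = fit_pca(X, variance_target=0.9, feature_names=list("abcd"))
        with pytest.raises(ValueError, match="schema_mismatch"):
            transform_pca(model, X, feature_names=list("abce"))

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_pca(np.ones((5, 3)), variance_target=0.7)

    def test_model_round_trips_through_file(self, tmp_path, rng):
        X = rng.normal(size=(20, 6))
        model, _ = fit_pca(X, variance_target=0.8)
        model.save(tmp_path / "model.json")
        loaded = PCAModel.load(tmp_path / "model.json")
        np.testing.assert_allclose(loaded.loadings, model.loadings)
        np.testing.assert_allclose(transform_pca(loaded, X), transform_pca(model, X))
        assert loaded.schema_hash == model.schema_hash


class TestTSNE:
    def test_seeded_runs_are_bit_identical(self, rng):
        scores = rng.normal(size=(120, 5))
        cfg = TSNEConfig(perplexity=20, steps=300, random_seed=0)
        a = fit_tsne(scores, cfg)
        b = fit_tsne(scores, cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.coords.shape == (120, 3)
        assert np.isfinite(a.coords).all()

    def test_two_blobs_stay_separated(self, rng):
        a = rng.normal(size=(100, 5)) + 20.0
        b = rng.normal(size=(100, 5)) - 20.0
        scores = np.vstack([a, b])
        labels = np.array([0] * 100 + [1] * 100)
        coords = fit_tsne(scores, TSNEConfig(perplexity=30, steps=500, random_seed=0))
        purity = _nn_purity(coords.coords, labels)
        assert purity >= 0.9

    def test_excessive_perplexity_rejected(self, rng):
        scores = rng.normal(size=(200, 4))
        with pytest.raises(ValueError, match="too_few_points"):
            fit_tsne(scores, TSNEConfig(perplexity=300, steps=300))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TSNEConfig(perplexity=-1)
        with pytest.raises(ValueError):
            TSNEConfig(steps=10)


def _nn_purity(coords: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    _, idx = nn.kneighbors(coords)
    return float((labels[idx[:, 1]] == labels).mean())


class TestPlacement:
    def _reference(self, rng, n=30):
        scores = rng.normal(size=(n, 4))
        coords = EmbeddingCoordinates(
            ids=[f"r{i}" for i in range(n)], coords=rng.normal(size=(n, 3))
        )
        return scores, coords

    def test_duplicate_of_reference_lands_exactly_on_it(self, rng):
        scores, coords = self._reference(rng)
        placed = place_user_points(coords, scores, scores[7][None, :], k_neighbors=5)
        np.testing.assert_array_equal(placed.coords[0], coords.coords[7])
        assert placed.provenance == ["user_placed"]

    def test_equidistant_pair_gives_midpoint(self):
        scores = np.array([[1.0, 0.0], [-1.0, 0.0]])
        coords = EmbeddingCoordinates(
            ids=["a", "b"], coords=np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        )
        placed = place_user_points(coords, scores, np.array([[0.0, 0.0]]), k_neighbors=2)
        np.testing.assert_allclose(placed.coords[0], [1.0, 1.0, 1.0])

    def test_empty_reference_rejected(self):
        coords = EmbeddingCoordinates(ids=[], coords=np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty_reference"):
            place_user_points(coords, np.empty((0, 2)), np.zeros((1, 2)))

    def test_held_out_subclass_members_land_among_their_kin(
        self, bench_records, bench_matrix, bench_pca
    ):
        model, scores = bench_pca
        labels = np.array([r.expected.subclass_label for r in bench_records])
        rng = np.random.default_rng(5)
        held = rng.choice(len(bench_records), size=20, replace=False)
        keep = np.setdiff1d(np.arange(len(bench_records)), held)
        coords = fit_tsne(
            scores[keep],
            TSNEConfig(perplexity=30, steps=500, random_seed=0),
            ids=[bench_records[i].id for i in keep],
        )
        placed = place_user_points(coords, scores[keep], scores[held], k_neighbors=5)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=1).fit(coords.coords)
        _, idx = nn.kneighbors(placed.coords)
        agree = labels[keep][idx[:, 0]] == labels[held]
        assert agree.mean() >= 0.8


class TestHomologousTrend:
    def test_some_component_tracks_chain_length(self, bench_records, bench_pca):
        from scipy.stats import spearmanr

        model, scores = bench_pca
        # linear perfluoroalkyl carboxylic acid series, 10 members
        series = [
            (i, r.expected.perfluoro_chain_length_n)
            for i, r in enumerate(bench_records)
            if r.expected.subclass_label == "PFCAs" and r.id.endswith("lin")
        ]
        assert len(series) >= 8
        rows = [i for i, _ in series]
        ns = [n for _, n in series]
        rhos = [abs(spearmanr(scores[rows, c], ns).statistic) for c in range(model.k)]
        assert max(rhos) >= 0.9
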
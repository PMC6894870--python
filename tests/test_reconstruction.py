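"""Autoencoder/PCA backends, reconstruction errors, threshold, partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aednns as A
from aednns.preprocessing import FeatureMatrix
from aednns.reconstruction import AE_ACTIVATIONS


def _standardized(rng, n, d):
    X = rng.normal(size=(n, d))
    X = (X - X.mean(0)) / X.std(0)
    return FeatureMatrix(X, [f"c{i}" for i in range(d)], standardized=True)


def _pca_re_oracle(values, n_components):
    """Eigen-decomposition reconstruction error, independent of the SVD path."""
    mu = values.mean(axis=0)
    C = np.cov(values - mu, rowvar=False, bias=True)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    top = evecs[:, np.argsort(evals)[::-1][:n_components]]
    proj = (values - mu) @ top @ top.T + mu
    return np.mean((values - proj) ** 2, axis=1)


class TestAutoencoder:
    def test_weight_shapes_follow_layer_widths(self, rng):
        X = _standardized(rng, 60, 14)
        spec = A.AutoencoderSpec(epochs=1)
        backend = A.fit_autoencoder(X, spec)
        shapes = [w.shape for w in backend.net.weights]
        assert shapes == [(14, 10), (10, 7), (7, 4), (4, 7), (7, 10), (10, 14)]
        assert backend.net.activations == AE_ACTIVATIONS

    def test_training_reduces_loss(self, rng):
        X = _standardized(rng, 500, 14)
        backend = A.fit_autoencoder(X, A.AutoencoderSpec(epochs=200))
        assert backend.loss_history[-1] <= backend.loss_history[0]

    def test_default_learning_rate(self):
        assert A.AutoencoderSpec().learning_rate == 0.001

    def test_final_loss_matches_mean_re(self, rng):
        # the optimizer's recorded final loss is the mean per-sample RE
        X = _standardized(rng, 200, 14)
        backend = A.fit_autoencoder(X, A.AutoencoderSpec(epochs=30))
        re = A.per_sample_re(backend, X)
        assert re.mean() == pytest.approx(backend.loss_history[-1], rel=1e-10)

    def test_seeded_fit_is_reproducible(self, rng):
        X = _standardized(rng, 100, 14)
        spec = A.AutoencoderSpec(epochs=10, seed=42)
        b1 = A.fit_autoencoder(X, spec)
        b2 = A.fit_autoencoder(X, spec)
        for w1, w2 in zip(b1.net.weights, b2.net.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_mismatched_widths_rejected(self, rng):
        X = _standardized(rng, 30, 14)
        with pytest.raises(ValueError):
            A.fit_autoencoder(X, A.AutoencoderSpec(layer_widths=[12, 10, 7, 4, 7, 10, 12]))


class TestPCABackend:
    def test_full_rank_reconstruction_exact(self, rng):
        X = _standardized(rng, 40, 5)
        backend = A.fit_pca_backend(X, 5)
        assert A.per_sample_re(backend, X).max() < 1e-12

    def test_collinear_data_zero_re(self):
        t = np.linspace(-2, 2, 30)
        X = FeatureMatrix(np.column_stack([t, 3 * t]), ["a", "b"])
        backend = A.fit_pca_backend(X, 1)
        assert A.per_sample_re(backend, X).max() < 1e-20

    def test_toy_point_re_matches_eigen_oracle(self):
        pts = np.array([[1, 1], [-1, -1], [2, 2], [-2, -2], [0, 1]], dtype=float)
        X = FeatureMatrix(pts, ["a", "b"])
        backend = A.fit_pca_backend(X, 1)
        re = A.per_sample_re(backend, X)
        np.testing.assert_allclose(re, _pca_re_oracle(pts, 1), atol=1e-10)

    def test_oracle_equivalence_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 21))
            d = int(rng.integers(2, 6))
            q = int(rng.integers(1, d + 1))
            vals = rng.normal(size=(n, d)) * rng.uniform(0.5, 3)
            X = FeatureMatrix(vals, [f"c{i}" for i in range(d)])
            re = A.per_sample_re(A.fit_pca_backend(X, q), X)
            np.testing.assert_allclose(re, _pca_re_oracle(vals, q), atol=1e-8)

    def test_components_out_of_range(self, rng):
        X = _standardized(rng, 10, 3)
        with pytest.raises(ValueError):
            A.fit_pca_backend(X, 0)
        with pytest.raises(ValueError):
            A.fit_pca_backend(X, 4)


class TestPerSampleRE:
    def test_hand_computed_value(self):
        backend = A.fit_pca_backend(
            FeatureMatrix(np.eye(3), list("abc")), 3
        )  # identity reconstruction
        x = np.array([[1.0, 0.0, 1.0]])
        xhat = np.array([[0.0, 0.0, 1.0]])
        assert np.mean((x - xhat) ** 2) == pytest.approx(1 / 3)
        # and the exact-reconstruction backend yields zero RE
        assert A.per_sample_re(backend, x)[0] < 1e-12

    def test_residual_scaling_is_quadratic(self, rng):
        vals = rng.normal(size=(15, 4))
        X = FeatureMatrix(vals, list("abcd"))
        backend = A.fit_pca_backend(X, 2)
        re1 = A.per_sample_re(backend, X)
        # scale residuals by c: move inputs to recon + c*(x - recon)
        recon = backend.reconstruct(vals)
        scaled = recon + 3.0 * (vals - recon)
        re3 = A.per_sample_re(backend, scaled)
        np.testing.assert_allclose(re3, 9.0 * re1, rtol=1e-8)

    def test_width_mismatch_rejected(self, rng):
        X = _standardized(rng, 10, 4)
        backend = A.fit_pca_backend(X, 2)
        with pytest.raises(ValueError):
            A.per_sample_re(backend, np.zeros((3, 5)))


class TestExtractREFeature:
    def test_risky_rows_score_lower_than_shifted_low_rows(self, rng):
        # generous capacity on two shifted distributions
        risky = rng.normal(0, 1, size=(300, 6))
        low = rng.normal(4, 1, size=(300, 6))
        X = FeatureMatrix(np.vstack([risky, low]), [f"c{i}" for i in range(6)])
        y = np.array([1] * 300 + [0] * 300)
        spec = A.AutoencoderSpec(layer_widths=[6, 5, 4, 3, 4, 5, 6], epochs=150)
        re, backend = A.extract_re_feature(X, y, spec)
        assert backend.fitted_on == "risky"
        assert re[:300].mean() < re[300:].mean()

    def test_empty_risky_subset_rejected(self, rng):
        X = _standardized(rng, 20, 14)
        with pytest.raises(ValueError, match="high-risk"):
            A.extract_re_feature(X, np.zeros(20), A.AutoencoderSpec(epochs=1))

    def test_deterministic_from_seed(self, rng):
        X = _standardized(rng, 50, 14)
        y = (rng.random(50) < 0.5).astype(int)
        spec = A.AutoencoderSpec(epochs=5, seed=9)
        re1, _ = A.extract_re_feature(X, y, spec)
        re2, _ = A.extract_re_feature(X, y, spec)
        np.testing.assert_array_equal(re1, re2)


class TestThresholdAndPartition:
    def test_constant_re_threshold_is_the_constant(self):
        th = A.compute_threshold(np.array([2.5, 2.5, 2.5]))
        assert th.value == pytest.approx(2.5)

    def test_sd_convention_hand_value(self):
        th = A.compute_threshold(np.array([1.0, 2.0, 3.0]), "standard_deviation")
        assert th.value == pytest.approx(2 + np.sqrt(2 / 3), abs=1e-12)

    def test_variance_convention_hand_value(self):
        th = A.compute_threshold(np.array([1.0, 2.0, 3.0]), "variance")
        assert th.value == pytest.approx(8 / 3, abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            A.compute_threshold(np.array([]))

    def test_ties_go_low(self):
        part = A.partition_by_re(np.array([1.0, 3.0, 5.0]), A.REThreshold(3.0))
        assert part.high_idx.tolist() == [2]
        assert part.low_idx.tolist() == [0, 1]

    def test_threshold_above_max_empties_high_group(self):
        part = A.partition_by_re(np.array([1.0, 2.0]), A.REThreshold(10.0))
        assert part.high_idx.size == 0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        st.sampled_from(["standard_deviation", "variance"]),
    )
    def test_threshold_dominates_mean_and_partition_covers(self, values, convention):
        re = np.array(values)
        th = A.compute_threshold(re, convention)
        assert th.value >= re.mean() - 1e-12
        part = A.partition_by_re(re, th)
        combined = np.concatenate([part.high_idx, part.low_idx])
        assert sorted(combined.tolist()) == list(range(len(re)))
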
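"""Information-geometry core: fits, FIM, KL, geodesic distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg
from scipy.spatial.distance import mahalanobis

from manifoldmri import (
    FeatureMatrix,
    GaussianParams,
    class_distance_matrix,
    fisher_information,
    fit_gaussian,
    geodesic_distance,
    kl_divergence,
)
from conftest import random_spd


class TestFitGaussian:
    def test_two_point_mle(self):
        p = fit_gaussian(np.array([[0.0, 0.0], [2.0, 2.0]]), epsilon=0.0)
        np.testing.assert_allclose(p.mu, [1.0, 1.0])
        np.testing.assert_allclose(p.sigma, [[1.0, 1.0], [1.0, 1.0]])

    def test_repeated_row_gives_pure_regularizer(self):
        X = np.tile([3.0, -1.0, 2.0], (7, 1))
        p = fit_gaussian(X, epsilon=1e-5)
        np.testing.assert_allclose(p.sigma, 1e-5 * np.eye(3), atol=1e-15)
        assert p.n_fit == 7

    def test_consistency_on_large_sample(self, rng):
        cov = random_spd(rng, 3)
        L = np.linalg.cholesky(cov)
        n = 10_000
        X = np.array([1.0, -2.0, 0.5]) + rng.standard_normal((n, 3)) @ L.T
        p = fit_gaussian(X, epsilon=0.0)
        sd = np.sqrt(np.diag(cov))
        assert np.all(np.abs(p.mu - [1.0, -2.0, 0.5]) < 4 * sd / np.sqrt(n))

    def test_biased_divisor(self, rng):
        X = rng.standard_normal((5, 2))
        p = fit_gaussian(X, epsilon=0.0)
        np.testing.assert_allclose(p.sigma, np.cov(X.T, bias=True), atol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.array([[1.0, np.nan]]))


class TestFisherInformation:
    def test_identity_covariance(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.eye(2))
        F = fisher_information(p)
        np.testing.assert_allclose(F.mean_block, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(F.cov_block, 0.5 * np.eye(4), atol=1e-12)

    def test_scalar_case(self):
        p = GaussianParams(mu=np.zeros(1), sigma=np.array([[2.0]]))
        F = fisher_information(p)
        np.testing.assert_allclose(F.mean_block, [[0.5]])
        np.testing.assert_allclose(F.cov_block, [[0.125]])

    def test_kron_structure_against_double_loop(self, rng):
        sigma = random_spd(rng, 3)
        p = GaussianParams(mu=np.zeros(3), sigma=sigma)
        F = fisher_information(p)
        inv = np.linalg.inv(sigma)
        d = 3
        brute = np.empty((d * d, d * d))
        for i in range(d):
            for j in range(d):
                for k in range(d):
                    for l in range(d):
                        brute[i * d + j, k * d + l] = 0.5 * inv[i, k] * inv[j, l]
        np.testing.assert_allclose(F.cov_block, brute, atol=1e-10)

    def test_blocks_positive_definite(self, rng):
        for _ in range(5):
            p = GaussianParams(mu=np.zeros(4), sigma=random_spd(rng, 4))
            F = fisher_information(p)
            assert np.min(np.linalg.eigvalsh(F.mean_block)) > 0
            assert np.min(np.linalg.eigvalsh(F.cov_block)) > 0

    def test_singular_sigma_rejected(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.zeros((2, 2)) + 0.0,
                           epsilon=0.0)
        with pytest.raises(ValueError, match="regulari"):
            fisher_information(p)


class TestKL:
    def test_self_divergence_zero(self, rng):
        p = GaussianParams(mu=rng.standard_normal(3), sigma=random_spd(rng, 3))
        assert abs(kl_divergence(p, p)) < 1e-10

    def test_unit_mean_shift(self):
        p = GaussianParams(mu=np.zeros(1), sigma=np.eye(1))
        q = GaussianParams(mu=np.ones(1), sigma=np.eye(1))
        assert kl_divergence(p, q) == pytest.approx(0.5)

    def test_variance_inflation_closed_form(self):
        # KL(N(0,1) || N(0,4)) = (ln 4 - 1 + 1/4) / 2, evaluated by hand
        p = GaussianParams(mu=np.zeros(1), sigma=np.eye(1))
        q = GaussianParams(mu=np.zeros(1), sigma=4.0 * np.eye(1))
        expected = 0.5 * (np.log(4.0) - 1.0 + 0.25)
        assert kl_divergence(p, q) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3181, abs=5e-5)

    def test_generically_asymmetric(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.eye(2))
        q = GaussianParams(mu=np.ones(2), sigma=3.0 * np.eye(2))
        assert kl_divergence(p, q) != pytest.approx(kl_divergence(q, p))

    def test_dimension_mismatch(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.eye(2))
        q = GaussianParams(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            kl_divergence(p, q)


class TestGeodesicDistance:
    def test_identical_gaussians(self, rng):
        p = GaussianParams(mu=rng.standard_normal(4), sigma=random_spd(rng, 4))
        assert geodesic_distance(p, p) == pytest.approx(0.0, abs=1e-8)

    def test_unit_cov_mean_shift_two(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.eye(2))
        q = GaussianParams(mu=np.array([2.0, 0.0]), sigma=np.eye(2))
        assert geodesic_distance(p, q) == pytest.approx(2.0)

    def test_variance_ratio_e_squared(self):
        p = GaussianParams(mu=np.zeros(1), sigma=np.eye(1))
        q = GaussianParams(mu=np.zeros(1), sigma=np.e ** 2 * np.eye(1))
        assert geodesic_distance(p, q) == pytest.approx(2.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            p = GaussianParams(mu=rng.standard_normal(5),
                               sigma=random_spd(rng, 5))
            q = GaussianParams(mu=rng.standard_normal(5),
                               sigma=random_spd(rng, 5))
            assert geodesic_distance(p, q) == pytest.approx(
                geodesic_distance(q, p), abs=1e-8
            )

    def test_equal_means_matches_spd_metric(self, rng):
        # equal means: distance reduces to ||logm(S0^-1/2 S1 S0^-1/2)||_F
        for _ in range(10):
            s0, s1 = random_spd(rng, 6), random_spd(rng, 6)
            p = GaussianParams(mu=np.zeros(6), sigma=s0)
            q = GaussianParams(mu=np.zeros(6), sigma=s1)
            inv_sqrt = linalg.fractional_matrix_power(s0, -0.5)
            oracle = np.linalg.norm(
                linalg.logm(inv_sqrt @ s1 @ inv_sqrt), "fro"
            )
            assert geodesic_distance(p, q) == pytest.approx(oracle, abs=1e-8)

    def test_equal_covs_matches_mahalanobis(self, rng):
        for _ in range(5):
            s = random_spd(rng, 4)
            mu0, mu1 = rng.standard_normal(4), rng.standard_normal(4)
            p = GaussianParams(mu=mu0, sigma=s)
            q = GaussianParams(mu=mu1, sigma=s)
            oracle = mahalanobis(mu0, mu1, np.linalg.inv(s))
            assert geodesic_distance(p, q) == pytest.approx(oracle, abs=1e-8)

    def test_affine_invariance(self, rng):
        # applying x -> Ax + b to both samples leaves the distance unchanged
        Xa = rng.standard_normal((200, 3)) + [1, 0, 0]
        Xb = 1.5 * rng.standard_normal((200, 3)) - [0, 2, 0]
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        d0 = geodesic_distance(fit_gaussian(Xa, 0.0), fit_gaussian(Xb, 0.0))
        d1 = geodesic_distance(fit_gaussian(Xa @ A.T + b, 0.0),
                               fit_gaussian(Xb @ A.T + b, 0.0))
        assert d1 == pytest.approx(d0, rel=1e-6)
        k0 = kl_divergence(fit_gaussian(Xa, 0.0), fit_gaussian(Xb, 0.0))
        k1 = kl_divergence(fit_gaussian(Xa @ A.T + b, 0.0),
                           fit_gaussian(Xb @ A.T + b, 0.0))
        assert k1 == pytest.approx(k0, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        p = GaussianParams(mu=np.zeros(2), sigma=np.eye(2))
        q = GaussianParams(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            geodesic_distance(p, q)


class TestMetricProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(d=st.integers(1, 6), seed=st.integers(0, 2 ** 20))
    def test_symmetry_nonnegativity_identity(self, d, seed):
        rng = np.random.default_rng(seed)
        p = GaussianParams(mu=rng.standard_normal(d), sigma=random_spd(rng, d))
        q = GaussianParams(mu=rng.standard_normal(d), sigma=random_spd(rng, d))
        dpq = geodesic_distance(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(geodesic_distance(q, p), abs=1e-8)
        assert geodesic_distance(p, p) == pytest.approx(0.0, abs=1e-7)
        assert kl_divergence(p, q) >= -1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(d=st.integers(1, 5), seed=st.integers(0, 2 ** 20))
    def test_fit_satisfies_invariants(self, d, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((max(2, d), d)) * rng.uniform(0.1, 10)
        p = fit_gaussian(X, epsilon=1e-5)
        w = np.linalg.eigvalsh(p.sigma)
        assert w.min() >= p.epsilon - 1e-12


class TestClassDistanceMatrix:
    def test_diagonal_zero_and_matches_pairwise(self, rng):
        X = rng.standard_normal((60, 3))
        labels = np.repeat(["a", "b", "c"], 20)
        fm = FeatureMatrix(X=X, labels=labels)
        D = class_distance_matrix(fm, epsilon=1e-5)
        assert list(D.index) == ["a", "b", "c"]
        np.testing.assert_allclose(np.diag(D.values), 0.0)
        np.testing.assert_allclose(D.values, D.values.T)
        pa = fit_gaussian(X[:20], 1e-5)
        pb = fit_gaussian(X[20:40], 1e-5)
        assert D.loc["a", "b"] == pytest.approx(geodesic_distance(pa, pb))

    def test_identical_distributions_near_zero(self, rng):
        # two classes drawn from one Gaussian: distance << within-class scale
        X = rng.standard_normal((4000, 4))
        labels = np.repeat(["a", "b"], 2000)
        fm = FeatureMatrix(X=X, labels=labels)
        D = class_distance_matrix(fm, epsilon=1e-5)
        assert D.loc["a", "b"] < 0.1 * np.sqrt(4)  # within-class scale ~ sqrt(d)

    def test_small_class_rejected(self, rng):
        fm = FeatureMatrix(X=rng.standard_normal((3, 2)),
                           labels=np.array(["a", "a", "b"]))
        with pytest.raises(ValueError):
            class_distance_matrix(fm)
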
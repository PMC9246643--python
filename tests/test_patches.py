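"""Patch extraction, the mixture prior, EM, and patch classification."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import ilrdd
from ilrdd import Image2D
from ilrdd.patches import PatchMatrix, merge_patch_matrices


def _place_back(pm: PatchMatrix) -> np.ndarray:
    """Independent reassembly: restore DC, place patches, average overlaps."""
    p = pm.patch_size
    num = np.zeros(pm.source_shape)
    cnt = np.zeros(pm.source_shape)
    blocks = pm.vectors + pm.dc_offsets[None, :]
    for i, (r, c) in enumerate(pm.positions):
        num[r : r + p, c : c + p] += blocks[:, i].reshape(p, p)
        cnt[r : r + p, c : c + p] += 1
    assert cnt.min() >= 1, "coverage must be total"
    return num / cnt


class TestExtractPatches:
    @pytest.mark.parametrize(
        "shape,p,stride,expected_m",
        [
            ((4, 4), 2, 2, 4),
            ((64, 64), 8, 1, 57 * 57),
            ((11, 11), 4, 3, 16),  # 7 % 3 != 0: one boundary anchor per axis
        ],
    )
    def test_patch_count(self, shape, p, stride, expected_m):
        img = Image2D(np.arange(np.prod(shape), dtype=float).reshape(shape))
        pm = ilrdd.extract_patches(img, p, stride)
        assert pm.n_patches == expected_m

    def test_boundary_patches_flagged(self):
        img = Image2D(np.zeros((11, 11)))
        pm = ilrdd.extract_patches(img, 4, 3)
        assert pm.boundary.sum() == 16 - 9
        assert set(map(tuple, pm.positions[pm.boundary][:, :1].tolist())) <= {
            (0,), (3,), (6,), (7,)
        }

    @pytest.mark.parametrize("p,stride", [(4, 4), (8, 4), (8, 3), (5, 2)])
    def test_lossless_decomposition(self, phantom64, p, stride):
        pm = ilrdd.extract_patches(phantom64, p, stride)
        np.testing.assert_allclose(
            _place_back(pm), phantom64.pixels, atol=1e-13
        )

    def test_vectors_are_dc_free(self, phantom64):
        pm = ilrdd.extract_patches(phantom64, 8, 4)
        np.testing.assert_allclose(pm.vectors.mean(axis=0), 0.0, atol=1e-12)

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ilrdd.extract_patches(Image2D(np.zeros((16, 16))), 17, 1)

    def test_merge_pools_columns(self, phantom64):
        pm = ilrdd.extract_patches(phantom64, 8, 8)
        merged = merge_patch_matrices([pm, pm])
        assert merged.n_patches == 2 * pm.n_patches
        np.testing.assert_array_equal(merged.vectors[:, : pm.n_patches], pm.vectors)


class TestComponentLogDensity:
    def _toy_prior(self, dim=4, k=2, seed=0):
        g = np.random.default_rng(seed)
        means = g.normal(size=(k, dim))
        covs = []
        for _ in range(k):
            a = g.normal(size=(dim, dim))
            covs.append(a @ a.T + 0.5 * np.eye(dim))
        return ilrdd.GMMPrior(
            weights=np.full(k, 1.0 / k), means=means,
            covariances=np.array(covs), patch_size=2,
        )

    def test_maximum_at_the_mean(self):
        prior = self._toy_prior()
        at_mean = ilrdd.component_log_density(prior.means[0], 0, prior)
        sign, logdet = np.linalg.slogdet(prior.covariances[0])
        assert sign > 0
        log_c = -0.5 * (4 * np.log(2 * np.pi) + logdet)
        assert at_mean == pytest.approx(log_c, rel=1e-12)
        off = ilrdd.component_log_density(prior.means[0] + 0.3, 0, prior)
        assert off < at_mean

    def test_matches_isotropic_closed_form(self):
        dim, s2 = 9, 0.07
        prior = ilrdd.GMMPrior(
            weights=np.array([1.0]), means=np.zeros((1, dim)),
            covariances=s2 * np.eye(dim)[None], patch_size=3,
        )
        v = np.linspace(-1, 1, dim)
        expected = -0.5 * (dim * np.log(2 * np.pi * s2) + v @ v / s2)
        got = ilrdd.component_log_density(v, 0, prior)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_full_covariance(self):
        prior = self._toy_prior(dim=6, seed=3)
        v = np.random.default_rng(1).normal(size=6)
        expected = multivariate_normal(prior.means[1], prior.covariances[1]).logpdf(v)
        assert ilrdd.component_log_density(v, 1, prior) == pytest.approx(
            expected, rel=1e-10
        )

    def test_density_integrates_to_one_in_2d(self):
        # Quadrature oracle: on a 2-dimensional patch vector the density
        # must integrate to 1 over a wide grid.
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        prior = ilrdd.GMMPrior(
            weights=np.array([1.0]), means=np.zeros((1, 2)),
            covariances=cov[None], patch_size=1,
        )
        grid = np.linspace(-2.0, 2.0, 201)
        step = grid[1] - grid[0]
        total = 0.0
        for u in grid:
            dens = [
                np.exp(ilrdd.component_log_density(np.array([u, v]), 0, prior))
                for v in grid
            ]
            total += np.sum(dens) * step * step
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_non_positive_definite_rejected(self):
        prior = ilrdd.GMMPrior(
            weights=np.array([1.0]), means=np.zeros((1, 2)),
            covariances=np.array([[[1.0, 2.0], [2.0, 1.0]]]), patch_size=1,
        )
        with pytest.raises(ValueError, match="positive definite"):
            ilrdd.component_log_density(np.zeros(2), 0, prior)


def _patches_from_vectors(vectors: np.ndarray, p: int) -> PatchMatrix:
    """Wrap bare (dim, m) vectors as a DC-free PatchMatrix for fitting."""
    m = vectors.shape[1]
    return PatchMatrix(
        vectors=vectors - vectors.mean(axis=0, keepdims=True),
        positions=np.zeros((m, 2), dtype=int),
        patch_size=p,
        stride=p,
        source_shape=(p, p),
        dc_offsets=vectors.mean(axis=0),
        boundary=np.zeros(m, dtype=bool),
    )


class TestFitGmmEm:
    def test_single_component_is_sample_moments(self, phantom64):
        pm = ilrdd.extract_patches(phantom64, 4, 4)
        prior = ilrdd.fit_gmm_em(pm, 1, seed=0)
        x = pm.vectors.T
        np.testing.assert_allclose(prior.means[0], x.mean(axis=0), atol=1e-10)
        cov = np.cov(x, rowvar=False, bias=True)
        ridge = 1e-6 * np.trace(cov) / cov.shape[0]
        np.testing.assert_allclose(
            prior.covariances[0], cov + ridge * np.eye(cov.shape[0]), atol=1e-9
        )

    def test_loglikelihood_nondecreasing(self, prior64):
        ll = prior64.log_likelihoods
        assert len(ll) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(ll, ll[1:]))

    def test_two_separated_clusters_recovered(self, rng):
        # Two spherical clusters 10 sigma apart: hard labels must recover
        # the true partition exactly.
        dim, n = 16, 120
        a = rng.normal(0, 0.1, size=(n, dim))
        b = rng.normal(0, 0.1, size=(n, dim)) + 1.0  # 40 sigma apart
        vectors = np.vstack([a, b]).T
        truth = np.repeat([0, 1], n)
        pm = PatchMatrix(
            vectors=vectors, positions=np.zeros((2 * n, 2), int),
            patch_size=4, stride=4, source_shape=(4, 4),
            dc_offsets=np.zeros(2 * n), boundary=np.zeros(2 * n, bool),
        )
        prior = ilrdd.fit_gmm_em(pm, 2, seed=1)
        labels = ilrdd.classify_patches(pm, prior).labels
        agreement = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agreement == 1.0

    def test_k_exceeding_patch_count_rejected(self, phantom64):
        pm = ilrdd.extract_patches(phantom64, 8, 8)
        with pytest.raises(ValueError, match="exceeds"):
            ilrdd.fit_gmm_em(pm, pm.n_patches + 1, seed=0)

    def test_weights_sum_to_one(self, prior64):
        assert prior64.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_covariances_positive_definite(self, prior64):
        for cov in prior64.covariances:
            np.linalg.cholesky(cov)

    def test_prior_roundtrip(self, prior64, tmp_path):
        path = tmp_path / "prior.npz"
        ilrdd.save_prior(prior64, path)
        loaded = ilrdd.load_prior(path)
        np.testing.assert_array_equal(loaded.weights, prior64.weights)
        np.testing.assert_array_equal(loaded.means, prior64.means)
        np.testing.assert_array_equal(loaded.covariances, prior64.covariances)
        assert loaded.patch_size == prior64.patch_size


class TestClassifyPatches:
    def test_patch_at_component_mean_gets_its_label(self, prior64):
        k = 3
        pm = _patches_from_vectors(prior64.means[[k]].T.copy(), 8)
        # equal-weight copy so the argmax is decided by the density alone
        eq = ilrdd.GMMPrior(
            weights=np.full(prior64.n_components, 1.0 / prior64.n_components),
            means=prior64.means, covariances=prior64.covariances, patch_size=8,
        )
        assignment = ilrdd.classify_patches(pm, eq)
        assert assignment.labels[0] == k

    def test_posterior_rows_sum_to_one(self, phantom64, prior64):
        pm = ilrdd.extract_patches(phantom64, 8, 8)
        assignment = ilrdd.classify_patches(pm, prior64)
        sums = np.exp(assignment.log_posteriors).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_matches_bruteforce_loop(self, phantom64):
        # Direct per-(patch, component) evaluation of the clustering
        # objective, no batch machinery.
        pm = ilrdd.extract_patches(phantom64, 4, 8)  # 64 patches
        prior = ilrdd.fit_gmm_em(pm, 4, seed=2)
        assignment = ilrdd.classify_patches(pm, prior)
        for i in range(pm.n_patches):
            scores = [
                np.log(prior.weights[k])
                + ilrdd.component_log_density(pm.vectors[:, i], k, prior)
                for k in range(4)
            ]
            assert assignment.labels[i] == int(np.argmax(scores))

    def test_matches_sklearn_prediction(self, phantom64, prior64):
        # Independent oracle: inject the same parameters into sklearn's
        # GaussianMixture and compare labels and per-sample log-likelihood.
        # Covariances are inflated by sigma^2 I (as when classifying noisy
        # patches) so both routes work at sane conditioning.
        from scipy.linalg import solve_triangular
        from sklearn.mixture import GaussianMixture

        covs = prior64.covariances + 0.03**2 * np.eye(64)[None]
        prior = ilrdd.GMMPrior(
            weights=prior64.weights, means=prior64.means,
            covariances=covs, patch_size=8,
        )
        pm = ilrdd.extract_patches(phantom64, 8, 4)
        gm = GaussianMixture(n_components=prior.n_components)
        gm.weights_ = prior.weights
        gm.means_ = prior.means
        gm.covariances_ = covs
        gm.precisions_cholesky_ = np.array(
            [
                solve_triangular(
                    np.linalg.cholesky(c), np.eye(64), lower=True
                ).T
                for c in covs
            ]
        )
        assignment = ilrdd.classify_patches(pm, prior)
        np.testing.assert_array_equal(
            assignment.labels, gm.predict(pm.vectors.T)
        )
        np.testing.assert_allclose(
            np.exp(assignment.log_posteriors).sum(axis=1), 1.0, atol=1e-9
        )

    def test_argmax_labels_maximize_joint_loglikelihood(self, phantom64, prior64):
        # Switching any single label away from the argmax cannot increase
        # the clustering log-likelihood.
        pm = ilrdd.extract_patches(phantom64, 8, 8)
        assignment = ilrdd.classify_patches(pm, prior64)
        joint = assignment.log_posteriors  # normalised, same argmax ordering
        best = joint[np.arange(pm.n_patches), assignment.labels]
        assert np.all(best[:, None] >= joint - 1e-12)

    def test_component_permutation_permutes_labels(self, phantom64, prior64):
        perm = np.roll(np.arange(prior64.n_components), 3)
        permuted = ilrdd.GMMPrior(
            weights=prior64.weights[perm], means=prior64.means[perm],
            covariances=prior64.covariances[perm], patch_size=8,
        )
        pm = ilrdd.extract_patches(phantom64, 8, 8)
        a = ilrdd.classify_patches(pm, prior64)
        b = ilrdd.classify_patches(pm, permuted)
        inverse = np.argsort(perm)
        np.testing.assert_array_equal(inverse[a.labels], b.labels)

    def test_patch_size_mismatch_rejected(self, phantom64, prior64):
        pm = ilrdd.extract_patches(phantom64, 4, 4)
        with pytest.raises(ValueError, match="patch size"):
            ilrdd.classify_patches(pm, prior64)
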
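"""Patch extraction and the Gaussian-mixture patch prior.

An image is cut into overlapping p x p blocks.  After removing each block's
mean (DC), the block vectors are modelled by a K-component Gaussian mixture

    p(v | Theta) = sum_k w_k N(v; mu_k, Sigma_k),

learned by expectation-maximisation on clean imagery.  Noisy patches are then
hard-clustered by maximum posterior log w_k + log N(v; mu_k, Sigma_k); the
clusters drive the low-rank denoising stage.

DC removal makes the clusters invariant to local brightness, which is the
standard convention for patch priors; the offsets are restored at
reconstruction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .phantom import Image2D, seed_stream

__all__ = [
    "PatchMatrix",
    "GMMPrior",
    "ClusterAssignment",
    "extract_patches",
    "merge_patch_matrices",
    "component_log_density",
    "fit_gmm_em",
    "classify_patches",
    "save_prior",
    "load_prior",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PatchMatrix:
    """Vectorised overlapping blocks of one image.

    ``vectors`` is p^2 x m (row-major flattening of each p x p block) with the
    per-patch mean already subtracted and stored in ``dc_offsets``.
    ``positions`` holds the 0-based (row, col) top-left anchors;
    ``boundary`` flags the extra patches anchored to the last valid row or
    column when the stride does not tile the image exactly, so that every
    pixel is covered by at least one patch.
    """

    vectors: np.ndarray
    positions: np.ndarray
    patch_size: int
    stride: int
    source_shape: tuple[int, int]
    dc_offsets: np.ndarray
    boundary: np.ndarray

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class GMMPrior:
    """Learned mixture parameters Theta = (w_k, mu_k, Sigma_k), k = 1..K.

    Weights sum to 1; every covariance is symmetric with smallest eigenvalue
    at least the ridge floor applied during fitting.  ``log_likelihoods``
    records the per-iteration total data log-likelihood of the EM run that
    produced the prior (empty for priors built by hand).
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    patch_size: int
    log_likelihoods: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1 within 1e-12")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "means", np.asarray(self.means, dtype=np.float64)
        )
        object.__setattr__(
            self, "covariances", np.asarray(self.covariances, dtype=np.float64)
        )

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ClusterAssignment:
    """Hard labels (0-based) and the full m x K posterior log-probabilities."""

    labels: np.ndarray
    log_posteriors: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.log_posteriors.shape[1]


def extract_patches(img: Image2D, patch_size: int, stride: int) -> PatchMatrix:
    """All grid-aligned p x p patches plus boundary-completion patches.

    Anchors run over ``range(0, H - p + 1, stride)`` per axis; when
    ``H - p`` is not a multiple of the stride an extra anchor at ``H - p``
    (flagged as boundary) completes the coverage, and likewise for columns.
    """
    h, w = img.shape
    p = patch_size
    if p > min(h, w):
        raise ValueError(f"patch size {p} exceeds image {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    def _anchors(extent: int) -> tuple[np.ndarray, np.ndarray]:
        grid = np.arange(0, extent - p + 1, stride)
        flags = np.zeros(grid.size, dtype=bool)
        if grid[-1] != extent - p:
            grid = np.append(grid, extent - p)
            flags = np.append(flags, True)
        return grid, flags

    rows, rflag = _anchors(h)
    cols, cflag = _anchors(w)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    positions = np.stack([rr.ravel(), cc.ravel()], axis=1)
    boundary = (rflag[:, None] | cflag[None, :]).ravel()

    # Gather patches as an (m, p*p) view-based stack, then transpose.
    windows = np.lib.stride_tricks.sliding_window_view(img.pixels, (p, p))
    blocks = windows[positions[:, 0], positions[:, 1]].reshape(-1, p * p)
    dc = blocks.mean(axis=1)
    vectors = (blocks - dc[:, None]).T.copy()
    return PatchMatrix(
        vectors=vectors,
        positions=positions,
        patch_size=p,
        stride=stride,
        source_shape=(h, w),
        dc_offsets=dc,
        boundary=boundary,
    )


def merge_patch_matrices(parts: list[PatchMatrix]) -> PatchMatrix:
    """Pool patches from several images (for prior training).

    Positions refer to each patch's own source image; the merged matrix is
    only meant for fitting, not for reconstruction.
    """
    if not parts:
        raise ValueError("no patch matrices to merge")
    first = parts[0]
    if any(p.patch_size != first.patch_size for p in parts):
        raise ValueError("patch sizes differ")
    return PatchMatrix(
        vectors=np.concatenate([p.vectors for p in parts], axis=1),
        positions=np.concatenate([p.positions for p in parts], axis=0),
        patch_size=first.patch_size,
        stride=first.stride,
        source_shape=first.source_shape,
        dc_offsets=np.concatenate([p.dc_offsets for p in parts]),
        boundary=np.concatenate([p.boundary for p in parts]),
    )


def _chol_log_densities(
    vectors: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> np.ndarray:
    """m x K matrix of component log-densities via Cholesky factors."""
    d, m = vectors.shape
    k = means.shape[0]
    out = np.empty((m, k))
    for j in range(k):
        try:
            chol = linalg.cholesky(covariances[j], lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                f"covariance of component {j} is not positive definite"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        dev = vectors - means[j][:, None]
        z = linalg.solve_triangular(chol, dev, lower=True)
        maha = np.einsum("ij,ij->j", z, z)
        out[:, j] = -0.5 * (d * _LOG_2PI + logdet + maha)
    return out


def component_log_density(
    patch_vec: np.ndarray, k: int, prior: GMMPrior
) -> float:
    """Log-density of one DC-removed patch under mixture component ``k``.

    log c - 1/2 (v - mu_k)^T Sigma_k^{-1} (v - mu_k), with the normaliser
    log c = -1/2 (p^2 log 2 pi + log det Sigma_k), computed through a
    Cholesky factorisation rather than an explicit inverse.
    """
    v = np.asarray(patch_vec, dtype=np.float64).reshape(-1, 1)
    if v.shape[0] != prior.means.shape[1]:
        raise ValueError("patch vector length does not match the prior")
    return float(
        _chol_log_densities(v, prior.means[k : k + 1], prior.covariances[k : k + 1])[
            0, 0
        ]
    )


def _ridge(cov: np.ndarray) -> np.ndarray:
    """Floor a covariance by epsilon*I with epsilon = 1e-6 trace/dim."""
    d = cov.shape[0]
    eps = 1e-6 * max(np.trace(cov) / d, np.finfo(np.float64).tiny)
    return cov + eps * np.eye(d)


def fit_gmm_em(
    patches: PatchMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> GMMPrior:
    """Fit the K-component patch mixture by EM.

    Initialisation draws K centres by a seeded k-means++ scheme; covariances
    start at the global sample covariance.  Iteration stops when the gain in
    per-sample log-likelihood drops below ``tol`` or after ``max_iter``
    rounds.  Covariances are floored by ridge regularisation on every M-step.
    A component whose responsibility mass collapses is reseeded from the
    patch the current model fits worst.
    """
    x = patches.vectors.T  # (m, d)
    m, d = x.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m:
        raise ValueError(f"K={K} exceeds the number of patches m={m}")

    rng = seed_stream(seed, "em-init")
    centres, _ = kmeans_plusplus(
        x, n_clusters=K, random_state=int(rng.integers(2**31))
    )
    base_cov = _ridge(np.cov(x, rowvar=False, bias=True).reshape(d, d))

    weights = np.full(K, 1.0 / K)
    means = centres.astype(np.float64)
    covs = np.empty((K, d, d))

    def m_step(resp: np.ndarray) -> None:
        nonlocal weights, means
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        means = (resp.T @ x) / nk[:, None]
        for j in range(K):
            if nk[j] < 2.0:  # too little mass for a stable covariance
                covs[j] = base_cov
                continue
            dev = x - means[j]
            cov = (resp[:, j][:, None] * dev).T @ dev / nk[j]
            covs[j] = _ridge(0.5 * (cov + cov.T))

    # Seed the first M-step with hard nearest-centre responsibilities, the
    # usual k-means-seeded start (a density E-step under a shared global
    # covariance would discount exactly the directions that separate the
    # clusters).
    d2 = ((x[:, None, :] - centres[None]) ** 2).sum(axis=2)
    resp = np.zeros((m, K))
    resp[np.arange(m), d2.argmin(axis=1)] = 1.0
    m_step(resp)

    history: list[float] = []
    prev_ll = -np.inf
    prev_params = None
    for it in range(max_iter):
        log_dens = _chol_log_densities(patches.vectors, means, covs)
        with np.errstate(divide="ignore"):
            weighted = log_dens + np.log(weights)[None, :]
        norm = logsumexp(weighted, axis=1)
        ll = float(norm.sum())
        if ll < prev_ll:
            # The ridge floor perturbs the exact M-step maximiser, so near
            # convergence the likelihood can dip marginally; stop and keep
            # the best-scoring parameters.
            logger.debug("EM stopped on ridge-induced dip at iteration %d", it)
            weights, means, covs = prev_params
            break
        history.append(ll)
        resp = np.exp(weighted - norm[:, None])

        nk = resp.sum(axis=0)
        empty = np.flatnonzero(nk < 1e-10)
        if empty.size:
            worst = np.argsort(norm)  # patches the mixture explains worst
            for rank, j in enumerate(empty):
                logger.warning("EM component %d empty; reseeding", j)
                i = worst[rank % m]
                resp[i, :] = 0.0
                resp[i, j] = 1.0  # sole owner of its worst-fit patch
                covs[j] = base_cov

        prev_params = (weights.copy(), means.copy(), covs.copy())
        m_step(resp)
        if it > 0 and (ll - prev_ll) / m < tol:
            break
        prev_ll = ll

    return GMMPrior(
        weights=weights,
        means=means,
        covariances=covs,
        patch_size=patches.patch_size,
        log_likelihoods=tuple(history),
    )


def classify_patches(
    patches: PatchMatrix, prior: GMMPrior
) -> ClusterAssignment:
    """Hard-cluster patches by maximum posterior log w_k + log p_k(v).

    Ties break toward the smallest component index.  The returned
    ``log_posteriors`` rows are normalised (their exponentials sum to 1).
    """
    if patches.patch_size != prior.patch_size:
        raise ValueError(
            "prior patch size does not match the extracted patches"
        )
    log_dens = _chol_log_densities(
        patches.vectors, prior.means, prior.covariances
    )
    with np.errstate(divide="ignore"):
        joint = log_dens + np.log(prior.weights)[None, :]
    log_post = joint - logsumexp(joint, axis=1)[:, None]
    labels = np.argmax(joint, axis=1)  # argmax takes the first maximum
    return ClusterAssignment(labels=labels, log_posteriors=log_post)


def save_prior(prior: GMMPrior, path) -> None:
    """Serialize a prior as a single .npz archive with a JSON header."""
    header = json.dumps(
        {
            "format": "ilrdd-gmm-prior",
            "version": 1,
            "patch_size": prior.patch_size,
            "n_components": prior.n_components,
        }
    )
    np.savez_compressed(
        path,
        header=np.frombuffer(header.encode("utf-8"), dtype=np.uint8),
        weights=prior.weights,
        means=prior.means,
        covariances=prior.covariances,
        log_likelihoods=np.asarray(prior.log_likelihoods),
    )


def load_prior(path) -> GMMPrior:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["header"]).decode("utf-8"))
        if header.get("format") != "ilrdd-gmm-prior":
            raise ValueError(f"{path} is not a serialized GMM prior")
        return GMMPrior(
            weights=archive["weights"],
            means=archive["means"],
            covariances=archive["covariances"],
            patch_size=int(header["patch_size"]),
            log_likelihoods=tuple(float(v) for v in archive["log_likelihoods"]),
        )
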
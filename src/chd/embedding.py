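"""Manifold embedding of the dissimilarity matrix into a latent coordinate.

The pairwise dissimilarities are interpreted as Euclidean distances in an
abstract high-dimensional "MDS space" (default D = 30) found by minimizing
the raw stress

    S = sum_{i<j} (d_ij - ||x_i - x_j||)^2

with SMACOF majorization.  If the particles lie on a curved low-dimensional
manifold in MDS space, Isomap replaces Euclidean by graph-geodesic distances
and re-embeds, "unrolling" the manifold.  Finally PCA projects onto the
axis of largest variance: the 1-D latent coordinate along which particles
are ordered by structural similarity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import skew

from .registration import DissimilarityMatrix

logger = logging.getLogger("chd")

__all__ = [
    "EmbeddingCoordinates",
    "LatentSpace",
    "DisconnectedGraphError",
    "stress",
    "mds_embed",
    "isomap_unroll",
    "isomap_applicable",
    "pca_project",
]


@dataclass
class EmbeddingCoordinates:
    """N x D abstract coordinates produced by one embedding stage."""

    coords: np.ndarray
    stage: str  # "mds" | "isomap" | "pca"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be an (N, D) matrix with D >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class LatentSpace:
    """Per-particle latent coordinate(s) with the PCA variance profile."""

    coordinate: np.ndarray
    variance_explained: np.ndarray
    second_coordinate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        v = self.variance_explained
        if v.size and not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError("variance_explained must sum to 1")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")


class DisconnectedGraphError(RuntimeError):
    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"k-nearest-neighbor graph has {n_components} connected components; "
            "increase k"
        )


def _dvalues(d) -> np.ndarray:
    return d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)


def stress(coords: EmbeddingCoordinates | np.ndarray, d) -> float:
    """Raw stress: sum over unique pairs of squared distance residuals."""
    X = coords.coords if isinstance(coords, EmbeddingCoordinates) else np.asarray(coords)
    D = _dvalues(d)
    if X.shape[0] != D.shape[0]:
        raise ValueError("coordinate / dissimilarity shape mismatch")
    iu = np.triu_indices(D.shape[0], 1)
    return float(((D[iu] - pdist(X)) ** 2).sum())


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the Gram matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(lam)
    if X.shape[1] < dims:  # pad if fewer positive eigenvalues than dims
        X = np.hstack([X, np.zeros((n, dims - X.shape[1]))])
    return X


def _smacof(D: np.ndarray, X0: np.ndarray, tol: float, max_iter: int):
    """SMACOF majorization (Guttman transform) with unit weights.

    Guaranteed monotone non-increasing raw stress; returns the coordinate
    matrix and the per-iteration stress history.
    """
    n = D.shape[0]
    X = X0.copy()
    iu = np.triu_indices(n, 1)

    def _stress(X):
        return float(((D[iu] - pdist(X)) ** 2).sum())

    history = [_stress(X)]
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / np.where(dist > 0, dist, 1.0), 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, 0.0)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = (Bmat @ X) / n
        s = _stress(X)
        history.append(s)
        prev = history[-2]
        if prev - s < tol * max(prev, 1e-300):
            break
    return X, np.asarray(history)


def mds_embed(
    d,
    dims: int = 30,
    tol: float = 1e-9,
    max_iter: int = 2000,
    rng_seed: int = 0,
    n_restarts: int = 1,
    return_history: bool = False,
):
    """Embed a dissimilarity matrix into ``dims``-dimensional MDS space.

    SMACOF stress majorization initialized from classical (Torgerson)
    scaling, plus ``n_restarts`` random restarts; the solution with the
    lowest raw stress wins.  Stops when the relative stress decrease falls
    below ``tol``.

    Parameters
    ----------
    d
        Symmetric nonnegative matrix with zero diagonal
        (:class:`~chd.registration.DissimilarityMatrix` or array).
    dims
        Embedding dimensionality; D = 30 is the working default, large
        enough that the residual stress of typical particle dissimilarity
        matrices is negligible.
    """
    D = _dvalues(d)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(rng_seed)
    inits = [_classical_mds(D, dims)]
    span = D.max() if D.max() > 0 else 1.0
    for _ in range(n_restarts):
        inits.append(rng.normal(scale=0.5 * span, size=(D.shape[0], dims)))
    best_X, best_hist = None, None
    for X0 in inits:
        X, hist = _smacof(D, X0, tol=tol, max_iter=max_iter)
        if best_hist is None or hist[-1] < best_hist[-1]:
            best_X, best_hist = X, hist
    emb = EmbeddingCoordinates(best_X, stage="mds")
    if return_history:
        return emb, best_hist
    return emb


def isomap_unroll(
    e: EmbeddingCoordinates,
    k: int = 4,
    tol: float = 1e-9,
    max_iter: int = 2000,
    rng_seed: int = 0,
    return_geodesics: bool = False,
):
    """Unroll a curved manifold in MDS space via geodesic re-embedding.

    Steps: (1) find the k nearest neighbors of every point by Euclidean
    distance; (2) connect the neighborhoods into a proximity graph
    (symmetrized by union: an edge exists if either endpoint lists the
    other); (3) compute all-pairs shortest-path distances with Euclidean
    edge lengths — the geodesic distance matrix; (4) re-embed that matrix
    with :func:`mds_embed` at the same dimensionality.

    Raises
    ------
    DisconnectedGraphError
        If the neighbor graph is not connected (reports the component
        count); a disconnected graph is never silently bridged.
    """
    X = e.coords
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < N")
    dist = squareform(pdist(X))
    # k nearest neighbors excluding self
    nn_idx = np.argsort(dist, axis=1)[:, 1 : k + 1]
    rows = np.repeat(np.arange(n), k)
    cols = nn_idx.ravel()
    W = csr_matrix((dist[rows, cols], (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # union symmetrization
    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(n_comp)
    geo = shortest_path(W, method="D", directed=False)
    emb = mds_embed(geo, dims=e.dims, tol=tol, max_iter=max_iter, rng_seed=rng_seed)
    out = EmbeddingCoordinates(emb.coords, stage="isomap")
    if return_geodesics:
        return out, geo
    return out


def _variance_profile(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    cov_eigs = np.linalg.svd(Xc, compute_uv=False) ** 2
    total = cov_eigs.sum()
    if total <= 0:
        return np.zeros(X.shape[1])
    v = np.zeros(X.shape[1])
    v[: cov_eigs.size] = cov_eigs / total
    return v


def isomap_applicable(e: EmbeddingCoordinates) -> bool:
    """Decide whether Isomap unrolling can reveal a low-dimensional manifold.

    True iff the successive differences between the variance-explained
    fractions of the first three principal axes, (v1 - v2) and (v2 - v3),
    both strictly exceed half of the mean variance explained per axis.  An
    isotropic point cloud (all axes alike) fails the test: unrolling cannot
    reduce its dimensionality.
    """
    if e.dims < 3:
        raise ValueError("applicability rule needs at least 3 dimensions")
    v = _variance_profile(e.coords)
    half_mean = 0.5 * v.mean()
    return bool((v[0] - v[1] > half_mean) and (v[1] - v[2] > half_mean))


def pca_project(e: EmbeddingCoordinates, n_components: int = 1) -> LatentSpace:
    """Project onto the top principal axes to form the latent space.

    Coordinates are mean-centered and projected onto the leading
    eigenvectors of the sample covariance.  The sign of each axis is fixed
    so its score distribution has nonnegative skewness (ties: first
    particle's score nonnegative) — the latent sign is otherwise arbitrary,
    and a deterministic convention keeps runs reproducible.  The full
    variance-explained profile (one fraction per embedding axis, summing to
    1) is returned alongside.
    """
    X = e.coords
    n, d = X.shape
    if not 1 <= n_components < n:
        raise ValueError("need N > n_components >= 1")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (S**2).sum()
    if total <= 1e-300:
        warnings.warn("degenerate (zero-variance) embedding; latent set to zeros")
        v = np.zeros(d)
        v[0] = 1.0
        return LatentSpace(np.zeros(n), v, np.zeros(n) if n_components > 1 else None)
    var = np.zeros(d)
    var[: S.size] = S**2 / total
    scores = U * S  # (n, r) principal-component scores
    for a in range(min(n_components, scores.shape[1])):
        s = scores[:, a]
        sk = skew(s) if np.ptp(s) > 0 else 0.0
        if sk < 0 or (sk == 0 and s[0] < 0):
            scores[:, a] = -s
    second = scores[:, 1] if n_components > 1 else None
    return LatentSpace(scores[:, 0], var, second)
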
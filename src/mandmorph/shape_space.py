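"""PCA of symmetric shape components and related shape-space utilities.

The symmetric components from the superimposition are flattened to an
n x (k*d) matrix, centred on the consensus, and eigendecomposed.  PC scores
serve as the shape variables of the downstream models; a retention
diagnostic checks how faithfully the first m scores preserve the pairwise
Procrustes distances.  ``size_adjust`` regresses shape on log centroid size
(pooled over coordinates) and returns the residual shapes for allometry-free
re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

__all__ = ["ShapePCA", "fit_pca", "retain", "size_adjust", "axis_extremes"]


@dataclass
class ShapePCA:
    """Principal components of flattened shape coordinates.

    ``loadings`` rows are orthonormal eigenvectors over the k*d coordinates;
    ``scores[i, j] = (x_i - consensus_flat) @ loadings[j]``.  A deterministic
    sign convention (largest-absolute loading element positive) fixes each
    axis direction.
    """

    scores: np.ndarray  # n x m
    loadings: np.ndarray  # m x (k*d)
    eigenvalues: np.ndarray  # m
    variance_fraction: np.ndarray  # m
    consensus: np.ndarray  # k x d
    landmark_shape: tuple[int, int]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def rank(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Fold scores back to flattened coordinates about the consensus."""
        scores = np.atleast_2d(scores)
        return self.consensus.reshape(1, -1) + scores @ self.loadings


def fit_pca(shapes: np.ndarray, consensus: Optional[np.ndarray] = None) -> ShapePCA:
    """PCA of flattened shapes (n x k x d or n x p).

    Centring is on the mean of the data (the consensus of the
    superimposition coincides with it up to convergence tolerance).
    Components with negligible eigenvalues (< 1e-12 of the total) are
    dropped.
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 3:
        landmark_shape = shapes.shape[1:]
        flat = shapes.reshape(shapes.shape[0], -1)
    elif shapes.ndim == 2:
        landmark_shape = (shapes.shape[1], 1)
        flat = shapes
    else:
        raise ValueError("shapes must be n x k x d or n x p")
    n = flat.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 specimens")
    mean = flat.mean(axis=0)
    centred = flat - mean
    # SVD route: numerically stable eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    keep = eigenvalues > max(total, 1.0) * 1e-12
    eigenvalues = eigenvalues[keep]
    Vt = Vt[keep]
    # sign convention: largest-|.| element of each loading positive
    for j in range(Vt.shape[0]):
        row = Vt[j]
        if row[np.argmax(np.abs(row))] < 0:
            Vt[j] = -row
    scores = centred @ Vt.T
    return ShapePCA(
        scores=scores,
        loadings=Vt,
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / total,
        consensus=mean.reshape(landmark_shape),
        landmark_shape=landmark_shape,
    )


def retain(pca: ShapePCA, m: int) -> tuple[np.ndarray, dict]:
    """First ``m`` PC score columns plus a faithfulness diagnostic.

    The diagnostic correlates pairwise Euclidean distances in the retained
    score space with the full-space (Procrustes) distances, and reports the
    cumulative variance fraction.
    """
    if not 1 <= m <= pca.rank:
        raise ValueError(f"m must be in [1, {pca.rank}], got {m}")
    scores_m = pca.scores[:, :m]
    d_full = pdist(pca.scores)  # isometric to the flattened coordinates
    d_m = pdist(scores_m)
    if np.allclose(d_full, d_m):
        r = 1.0
    else:
        r = float(pearsonr(d_m, d_full)[0])
    diagnostic = {
        "distance_correlation": r,
        "cumulative_variance_fraction": float(pca.variance_fraction[:m].sum()),
        "m": m,
    }
    return scores_m, diagnostic


def size_adjust(
    shapes: np.ndarray,
    size: np.ndarray,
    permutations: int = 9999,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Residual shapes from the pooled multivariate regression of shape
    coordinates on (log centroid) size.

    R² is the predicted sum of squares over the total sum of squares pooled
    across coordinates; the p-value permutes the size labels, counting the
    observed statistic among the permutations.
    Returns ``(residual_shapes, r2, p)`` with residuals about the mean shape
    (i.e. mean + residual), in the input's array layout.
    """
    shapes = np.asarray(shapes, dtype=float)
    orig_shape = shapes.shape
    flat = shapes.reshape(orig_shape[0], -1)
    size = np.asarray(size, dtype=float)
    n = flat.shape[0]
    if n <= 2:
        raise ValueError("size_adjust requires n > 2")
    if size.std() == 0.0:
        raise ValueError("size vector is constant")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")

    x = size - size.mean()
    Y = flat - flat.mean(axis=0)
    ss_tot = float(np.sum(Y**2))
    xx = float(x @ x)

    def r2_of(xv: np.ndarray) -> float:
        beta = (xv @ Y) / xx  # p-vector of slopes
        return float(xx * np.sum(beta**2)) / ss_tot

    r2 = r2_of(x)
    rng = np.random.default_rng(seed)
    count = 1  # observed counted among permutations
    for _ in range(permutations):
        if r2_of(rng.permutation(x)) >= r2:
            count += 1
    p = count / (permutations + 1)

    fitted = np.outer(x, (x @ Y) / xx)
    residual = (Y - fitted) + flat.mean(axis=0)
    return residual.reshape(orig_shape), r2, p


def axis_extremes(
    pca: ShapePCA, axis: int, magnitude: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Shapes at ±``magnitude`` standard deviations along one PC axis,
    folded back to k x d landmark coordinates (wireframe endpoints)."""
    if not 0 <= axis < pca.rank:
        raise ValueError(f"axis must be in [0, {pca.rank - 1}], got {axis}")
    disp = magnitude * np.sqrt(pca.eigenvalues[axis]) * pca.loadings[axis]
    minus = (pca.consensus.reshape(-1) - disp).reshape(pca.landmark_shape)
    plus = (pca.consensus.reshape(-1) + disp).reshape(pca.landmark_shape)
    return minus, plus
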
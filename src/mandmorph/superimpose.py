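"""Generalized Procrustes analysis with object-symmetry decomposition.

Partial Procrustes convention throughout: every configuration is centred and
scaled to unit centroid size, and only proper rotations are used in the
fitting, so reflections can never masquerade as shape similarity.

Object symmetry: each specimen's reflected-and-relabelled copy (first
coordinate axis negated, paired landmark labels swapped) enters the
superimposition alongside the original.  The symmetric component of a
specimen is the average of its two aligned copies, the asymmetric component
half their difference, so ``aligned = symmetric + asymmetric`` exactly.

The consensus orientation is made deterministic: with symmetry enabled the
sagittal plane is rotated onto the first coordinate plane (left side
positive) and the within-plane axes onto the remaining principal axes; a
fixed sign rule breaks the remaining ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration
from .scheme import LandmarkScheme

__all__ = [
    "centroid_size",
    "center",
    "opa_align",
    "reflect_relabel",
    "gpa",
    "procrustes_distance",
    "tangent_project",
    "AlignedShapeSet",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared deviations of landmarks from their
    centroid — the standard geometric-morphometric size measure."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size <= 0.0 or not np.isfinite(size):
        raise ValueError("degenerate configuration: zero centroid size")
    return size


def center(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def _unit(coords: np.ndarray) -> np.ndarray:
    centred = center(coords)
    return centred / centroid_size(centred)


def _kabsch(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper (det = +1) least-squares rotation taking ``moving`` onto
    ``target``; both centred k x d arrays."""
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    d = H.shape[0]
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(d)
    D[-1, -1] = sign
    if np.linalg.matrix_rank(H, tol=1e-12) < d - 1:
        raise ValueError("degenerate configuration: rank-deficient alignment")
    return U @ D @ Vt


def opa_align(
    moving: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of one centred configuration onto
    another.

    Both inputs are scaled to unit centroid size; the returned configuration
    is the rotated unit-size ``moving`` and the residual is the root summed
    squared difference from unit-size ``target`` (the partial Procrustes
    distance of the pair).
    """
    m = _unit(np.asarray(moving, float))
    t = _unit(np.asarray(target, float))
    if m.shape != t.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {t.shape}")
    R = _kabsch(m, t)
    aligned = m @ R
    residual = float(np.linalg.norm(aligned - t))
    return aligned, residual


def reflect_relabel(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Mirror a configuration across the plane normal to the first axis and
    swap the left/right landmark labels."""
    out = np.asarray(coords, float).copy()
    out[:, 0] = -out[:, 0]
    return out[scheme.relabel_permutation()]


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared coordinate difference between two superimposed
    shapes (partial Procrustes convention: shapes must come from the same
    superimposition)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"scheme/shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def tangent_project(flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection of flattened shapes onto the tangent space at
    the (unit-size) consensus."""
    c = np.asarray(consensus_flat, float)
    c = c / np.linalg.norm(c)
    flat = np.atleast_2d(np.asarray(flat, float))
    coef = flat @ c - 1.0
    return flat - np.outer(coef, c)


@dataclass
class AlignedShapeSet:
    """Output of the generalized Procrustes superimposition."""

    aligned: np.ndarray  # n x k x d
    symmetric: np.ndarray  # n x k x d
    asymmetric: np.ndarray  # n x k x d
    mean_shape: np.ndarray  # k x d
    centroid_size: np.ndarray  # n
    scheme: LandmarkScheme
    specimen_ids: list[str]
    iterations: int = 0
    residual_trace: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def log_centroid_size(self) -> np.ndarray:
        return np.log(self.centroid_size)

    def flat(self, component: str = "symmetric", tangent: bool = False) -> np.ndarray:
        """Flattened n x (k*d) coordinates of a component, optionally
        projected to the tangent space at the consensus."""
        arr = getattr(self, component)
        flat = arr.reshape(self.n, -1)
        if tangent:
            flat = tangent_project(flat, self.mean_shape.reshape(-1))
        return flat

    def distances_to_mean(self, component: str = "aligned") -> np.ndarray:
        flat = self.flat(component)
        return np.linalg.norm(flat - self.mean_shape.reshape(1, -1), axis=1)

    def pairwise_distances(self, component: str = "aligned") -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.flat(component)))


def _orient_full(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus principal axes onto the
    coordinate axes with a deterministic sign rule."""
    d = consensus.shape[1]
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0), full_matrices=True)
    V = Vt.T
    rotated = consensus @ V
    signs = np.ones(d)
    for j in range(d - 1):
        col = rotated[:, j]
        signs[j] = np.sign(col[np.argmax(np.abs(col))]) or 1.0
    V = V * signs
    if np.linalg.det(V) < 0:
        V[:, -1] = -V[:, -1]
    return V


def _orient_symmetric(
    consensus: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Orientation rotation that keeps the sagittal plane on the first
    coordinate plane: only the within-plane axes are rotated to principal
    axes (3D); a sign rule fixes them."""
    d = consensus.shape[1]
    if d == 2:
        return np.eye(2)
    yz = consensus[:, 1:]
    cov = np.cov(yz.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    V2 = evecs[:, order]
    col0 = yz @ V2[:, 0]
    s0 = np.sign(col0[np.argmax(np.abs(col0))]) or 1.0
    V2[:, 0] *= s0
    # second axis fixed perpendicular with det +1
    V2[:, 1] = np.array([-V2[1, 0], V2[0, 0]])
    R = np.eye(3)
    R[1:, 1:] = V2
    return R


def _canonicalize_symmetry(
    consensus: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Rotate a near-symmetric consensus so its symmetry plane becomes the
    first coordinate plane (x = 0), left-side landmarks at positive x."""
    refl = reflect_relabel(consensus, scheme)
    Q = _kabsch(_unit(refl), _unit(consensus))
    d = consensus.shape[1]
    F = np.eye(d)
    F[0, 0] = -1.0
    G = F @ Q  # approximate reflection operator in coordinate space
    Gs = 0.5 * (G + G.T)
    evals, evecs = np.linalg.eigh(Gs)
    n = evecs[:, np.argmin(evals)]  # normal of the symmetry plane
    # left-side labels get positive first coordinate
    s = 0.0
    for left, right in scheme.pairs:
        s += consensus[left] @ n - consensus[right] @ n
    if s < 0:
        n = -n
    # complete n to a proper rotation, new first axis = n
    basis = np.linalg.qr(
        np.column_stack([n] + [np.eye(d)[:, j] for j in range(d)])
    )[0][:, :d]
    if basis[:, 0] @ n < 0:
        basis = -basis
    if np.linalg.det(basis) < 0:
        basis[:, -1] = -basis[:, -1]
    return basis


def _symmetrize(consensus: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Project onto exact reflect-relabel symmetry (plane already at x=0)."""
    return 0.5 * (consensus + reflect_relabel(consensus, scheme))


def gpa(
    configs: Sequence[LandmarkConfiguration],
    reflect_relabel_symmetry: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> AlignedShapeSet:
    """Generalized Procrustes analysis of a set of configurations.

    With ``reflect_relabel_symmetry`` each specimen contributes its original
    and its reflected-relabelled copy, yielding the object-symmetry
    decomposition into symmetric and asymmetric components.

    Raises on non-convergence after ``max_iter`` iterations (the residual
    trace is attached to the error message).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    scheme = configs[0].scheme
    for c in configs[1:]:
        if c.scheme is not scheme and c.scheme != scheme:
            raise ValueError("all configurations must share one scheme")
    sizes = np.array([centroid_size(c.coords) for c in configs])
    units = [_unit(c.coords) for c in configs]
    if reflect_relabel_symmetry:
        work = units + [_unit(reflect_relabel(u, scheme)) for u in units]
    else:
        work = list(units)

    consensus = work[0].copy()
    trace: list[float] = []
    aligned = work
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = [m @ _kabsch(m, consensus) for m in work]
        new = np.mean(aligned, axis=0)
        new = _unit(new)
        change = float(
            np.sqrt(np.mean((new - consensus) ** 2))
        )
        trace.append(change)
        consensus = new
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations; residual trace "
            f"tail {trace[-5:]}"
        )

    if reflect_relabel_symmetry:
        # rotate the symmetry plane onto x = 0 and enforce exact symmetry
        R0 = _canonicalize_symmetry(consensus, scheme)
        consensus = _unit(_symmetrize(consensus @ R0, scheme))
        for _ in range(max_iter):
            aligned = [m @ _kabsch(m, consensus) for m in work]
            new = _unit(_symmetrize(_unit(np.mean(aligned, axis=0)), scheme))
            change = float(np.sqrt(np.mean((new - consensus) ** 2)))
            trace.append(change)
            consensus = new
            if change < tol:
                break
        R_or = _orient_symmetric(consensus, scheme)
    else:
        R_or = _orient_full(consensus)

    consensus = consensus @ R_or
    if reflect_relabel_symmetry:
        consensus = _symmetrize(consensus, scheme)
    aligned = [m @ _kabsch(m, consensus) for m in work]

    n = len(configs)
    aligned_arr = np.stack(aligned[:n])
    if reflect_relabel_symmetry:
        reflected_arr = np.stack(aligned[n:])
        symmetric = 0.5 * (aligned_arr + reflected_arr)
        asymmetric = 0.5 * (aligned_arr - reflected_arr)
        mean_shape = _symmetrize(np.mean(aligned, axis=0), scheme)
    else:
        symmetric = aligned_arr.copy()
        asymmetric = np.zeros_like(aligned_arr)
        mean_shape = np.mean(aligned, axis=0)

    return AlignedShapeSet(
        aligned=aligned_arr,
        symmetric=symmetric,
        asymmetric=asymmetric,
        mean_shape=mean_shape,
        centroid_size=sizes,
        scheme=scheme,
        specimen_ids=[c.specimen_id for c in configs],
        iterations=n_iter,
        residual_trace=trace,
    )
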
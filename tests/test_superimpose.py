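"""Procrustes superimposition: OPA, GPA, symmetry decomposition, distances."""

import numpy as np
import pytest

from mandmorph.landmark_io import LandmarkConfiguration
from mandmorph.superimpose import (
    AlignedShapeSet,
    centroid_size,
    gpa,
    opa_align,
    procrustes_distance,
    reflect_relabel,
    tangent_project,
)

from conftest import random_configs


def naive_gpa(arrays, tol=1e-12, max_iter=500):
    """Independent minimal GPA: centre, unit-scale, iterate align-to-mean.

    Deliberately simple and separate from the library implementation; no
    symmetry handling, no orientation convention.
    """

    def unit(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())

    def rot(m, t):
        u, _, vt = np.linalg.svd(m.T @ t)
        d = np.sign(np.linalg.det(u @ vt))
        fix = np.eye(m.shape[1])
        fix[-1, -1] = d
        return u @ fix @ vt

    shapes = [unit(a) for a in arrays]
    consensus = shapes[0]
    for _ in range(max_iter):
        shapes = [s @ rot(s, consensus) for s in shapes]
        new = unit(np.mean(shapes, axis=0))
        if np.sqrt(((new - consensus) ** 2).mean()) < tol:
            consensus = new
            break
        consensus = new
    return shapes, consensus


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], float)
        assert centroid_size(square) == pytest.approx(2 * np.sqrt(2))

    def test_homogeneous_in_scale(self, rng):
        coords = rng.standard_normal((28, 3))
        assert centroid_size(3.7 * coords) == pytest.approx(
            3.7 * centroid_size(coords)
        )

    def test_matches_direct_formula(self, rng):
        coords = rng.standard_normal((28, 3)) * 10
        centred = coords - coords.mean(axis=0)
        expected = np.sqrt(sum(np.sum(row**2) for row in centred))
        assert centroid_size(coords) == pytest.approx(expected, rel=1e-12)

    def test_coincident_landmarks_error(self):
        with pytest.raises(ValueError, match="zero centroid size"):
            centroid_size(np.ones((5, 3)))


class TestOPA:
    def test_exact_recovery_of_rotated_copy(self, rng):
        base = rng.standard_normal((28, 3))
        base -= base.mean(axis=0)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, -1] = -Q[:, -1]
        _, residual = opa_align(base @ Q, base)
        assert residual < 1e-10

    def test_reflection_not_allowed(self, rng):
        base = rng.standard_normal((10, 3))
        base -= base.mean(axis=0)
        mirrored = base.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        _, residual = opa_align(mirrored, base)
        assert residual > 1e-3  # chiral configuration cannot be matched

    def test_matches_grid_search_in_2d(self, rng):
        """Dense search over rotation angles is the oracle for the optimal
        residual of a 2D pair."""
        a = rng.standard_normal((6, 2))
        b = rng.standard_normal((6, 2))

        def unit(x):
            x = x - x.mean(axis=0)
            return x / np.sqrt((x**2).sum())

        ua, ub = unit(a), unit(b)
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 200_001):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            best = min(best, np.linalg.norm(ua @ R - ub))
        _, residual = opa_align(a, b)
        assert residual == pytest.approx(best, abs=1e-6)

    def test_degenerate_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|rank"):
            opa_align(line, line[::-1])


class TestGPA:
    def test_similarity_copies_have_zero_distances(self, scheme, template, rng):
        configs = []
        for i in range(5):
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, -1] = -Q[:, -1]
            coords = template @ Q * rng.uniform(0.5, 2.0) + rng.uniform(-30, 30, 3)
            configs.append(LandmarkConfiguration(f"s{i}", coords, scheme))
        aligned = gpa(configs)
        assert aligned.pairwise_distances("aligned").max() < 1e-8

    def test_symmetric_specimen_has_no_asymmetry(self, scheme, template):
        configs = [
            LandmarkConfiguration("a", template, scheme),
            LandmarkConfiguration("b", template * 1.3, scheme),
        ]
        aligned = gpa(configs)
        assert np.abs(aligned.asymmetric).max() < 1e-10

    def test_matches_independent_naive_gpa(self, small_scheme, rng):
        """Consensus and pairwise distances agree with a separately coded
        naive iterative GPA (no symmetry, so compare with symmetry off)."""
        arrays = [rng.standard_normal((5, 3)) * 5 for _ in range(3)]
        configs = [
            LandmarkConfiguration(f"s{i}", a, small_scheme)
            for i, a in enumerate(arrays)
        ]
        aligned = gpa(configs, reflect_relabel_symmetry=False)
        shapes, consensus = naive_gpa(arrays)
        # orientation conventions differ: compare rotation-invariant results
        for i in range(3):
            for j in range(i + 1, 3):
                ours = procrustes_distance(aligned.aligned[i], aligned.aligned[j])
                theirs = np.linalg.norm(shapes[i] - shapes[j])
                assert ours == pytest.approx(theirs, abs=1e-8)
        _, res = opa_align(aligned.mean_shape, consensus)
        assert res < 1e-7

    def test_symmetric_component_reflect_invariant(self, scheme, tiny_dataset):
        aligned = gpa(tiny_dataset.configs[:20])
        for i in range(0, 20, 5):
            sym = aligned.symmetric[i]
            resid = np.linalg.norm(reflect_relabel(sym, scheme) - sym)
            assert resid < 1e-8 * np.linalg.norm(sym)

    def test_decomposition_reconstructs_aligned(self, tiny_dataset):
        aligned = gpa(tiny_dataset.configs[:15])
        np.testing.assert_allclose(
            aligned.symmetric + aligned.asymmetric, aligned.aligned, atol=1e-12
        )

    def test_mean_of_aligned_is_mean_shape(self, tiny_dataset):
        aligned = gpa(tiny_dataset.configs[:15])
        # with symmetry, the consensus is the (symmetrized) mean over both
        # copies = mean of the symmetric components
        np.testing.assert_allclose(
            aligned.symmetric.mean(axis=0), aligned.mean_shape, atol=1e-9
        )

    def test_fixed_point(self, scheme, tiny_dataset):
        aligned = gpa(tiny_dataset.configs[:10])
        configs2 = [
            LandmarkConfiguration(s, c, scheme)
            for s, c in zip(aligned.specimen_ids, aligned.aligned)
        ]
        again = gpa(configs2)
        assert np.abs(again.aligned - aligned.aligned).max() < 1e-9

    def test_rigid_motion_invariance_of_distances(self, scheme, tiny_dataset, rng):
        configs = tiny_dataset.configs[:12]
        aligned = gpa(configs)
        moved = []
        for c in configs:
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, -1] = -Q[:, -1]
            moved.append(
                LandmarkConfiguration(
                    c.specimen_id,
                    c.coords @ Q * rng.uniform(0.2, 5.0) + rng.uniform(-100, 100, 3),
                    scheme,
                )
            )
        aligned2 = gpa(moved)
        d1 = aligned.pairwise_distances("aligned")
        d2 = aligned2.pairwise_distances("aligned")
        assert np.abs(d1 - d2).max() < 1e-8

    def test_order_invariance_of_distances(self, tiny_dataset):
        configs = tiny_dataset.configs[:12]
        d1 = gpa(configs).pairwise_distances("aligned")
        perm = [7, 2, 9, 0, 4, 11, 1, 3, 10, 6, 5, 8]
        d2 = gpa([configs[i] for i in perm]).pairwise_distances("aligned")
        assert np.abs(d1[np.ix_(perm, perm)] - d2).max() < 1e-9


class TestDistances:
    def test_identity_and_symmetry(self, rng):
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)

    def test_two_shape_distance_equals_opa_residual(self, tiny_dataset):
        aligned = gpa(tiny_dataset.configs[:5])
        a, b = aligned.aligned[0], aligned.aligned[1]
        _, residual = opa_align(a, b)
        # shapes already mutually aligned via the consensus: distances agree
        # with the pairwise optimum to superimposition accuracy
        assert procrustes_distance(a, b) == pytest.approx(residual, abs=1e-3)

    def test_triangle_inequality(self, tiny_dataset, rng):
        aligned = gpa(tiny_dataset.configs[:10])
        flat = aligned.flat("aligned")
        for _ in range(25):
            i, j, k = rng.choice(10, 3, replace=False)
            dij = np.linalg.norm(flat[i] - flat[j])
            djk = np.linalg.norm(flat[j] - flat[k])
            dik = np.linalg.norm(flat[i] - flat[k])
            assert dik <= dij + djk + 1e-9

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(np.zeros((5, 3)), np.zeros((6, 3)))


def test_tangent_projection_is_idempotent(tiny_dataset):
    aligned = gpa(tiny_dataset.configs[:8])
    c = aligned.mean_shape.reshape(-1)
    flat = aligned.flat("symmetric")
    once = tangent_project(flat, c)
    twice = tangent_project(once, c)
    np.testing.assert_allclose(once, twice, atol=1e-12)
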
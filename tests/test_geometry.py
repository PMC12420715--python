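"""Unit tests for the per-voxel hypersurface geometry."""

import numpy as np
import pytest

from ricciseg import geometry
from ricciseg.flow import gradient_field

from conftest import band_limited_gradient


def random_vector_field(rng, n=8, scale=1.0):
    return scale * rng.standard_normal((3, n, n, n))


class TestMetric:
    def test_inverse_is_exact(self, rng):
        v = random_vector_field(rng)
        g, g_inv, _ = geometry.metric_from_gradient(v)
        prod = np.einsum("ij...,jk...->ik...", g, g_inv)
        eye = np.eye(3).reshape(3, 3, 1, 1, 1)
        assert np.abs(prod - eye).max() < 1e-12

    def test_determinant_matrix_lemma(self, rng):
        v = random_vector_field(rng, scale=3.0)
        g, _, detg = geometry.metric_from_gradient(v)
        brute = np.linalg.det(np.moveaxis(g, (0, 1), (-2, -1)))
        assert np.abs(detg - brute).max() < 1e-10
        assert np.abs(detg - (1.0 + geometry.grad_norm_sq(v))).max() < 1e-12

    def test_metric_is_symmetric_positive_definite(self, rng):
        v = random_vector_field(rng, scale=2.0)
        g, _, _ = geometry.metric_from_gradient(v)
        assert np.abs(g - np.swapaxes(g, 0, 1)).max() == 0.0
        eig = np.linalg.eigvalsh(np.moveaxis(g, (0, 1), (-2, -1)))
        assert eig.min() >= 1.0 - 1e-12  # rank-one update of the identity

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            geometry.metric_from_gradient(np.zeros((2, 4, 4, 4)))
        with pytest.raises(ValueError, match="non-finite"):
            v = np.zeros((3, 4, 4, 4))
            v[1, 2, 3, 1] = np.nan
            geometry.metric_from_gradient(v)


class TestHessian:
    def test_symmetric_by_default(self, rng):
        v = random_vector_field(rng)
        H = geometry.hessian_from_gradient(v)
        assert np.abs(H - np.swapaxes(H, 0, 1)).max() == 0.0

    def test_exact_for_quadratic_level_set(self):
        # u = x^2 + 2 y^2 + 3 z^2 + xy: central differences are exact on
        # quadratics, so H equals the constant true Hessian in the interior.
        n = 9
        x, y, z = np.indices((n, n, n), dtype=float)
        u = x**2 + 2 * y**2 + 3 * z**2 + x * y
        v = gradient_field(u)
        H = geometry.hessian_from_gradient(v)
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 4.0, 0.0], [0.0, 0.0, 6.0]])
        # two-voxel rim: v is distorted on the faces by the Neumann padding
        # and H at the next layer reads those face values
        interior = (slice(2, -2),) * 3
        err = np.abs(H[(slice(None), slice(None)) + interior] - expected.reshape(3, 3, 1, 1, 1))
        assert err.max() < 1e-10

    def test_spacing_scales_derivatives(self, rng):
        v = random_vector_field(rng)
        H1 = geometry.hessian_from_gradient(v, (1.0, 1.0, 1.0))
        H2 = geometry.hessian_from_gradient(v, (2.0, 2.0, 2.0))
        assert np.allclose(H1, 2.0 * H2)

    def test_invalid_spacing_rejected(self, rng):
        v = random_vector_field(rng)
        with pytest.raises(ValueError, match="spacing"):
            geometry.hessian_from_gradient(v, (1.0, -1.0, 1.0))


class TestCurvatureClosedForms:
    def test_quadratic_bowl_center_values(self):
        # u = |x|^2/2 has H = I and grad u = 0 at the origin, giving
        # Ric = 2 I, R = 6 and Einstein tensor G = R g - 2 Ric = 2 I there.
        n = 9
        c = n // 2
        x, y, z = np.indices((n, n, n), dtype=float)
        u = 0.5 * ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        v = gradient_field(u)
        g, g_inv, detg = geometry.metric_from_gradient(v)
        H = geometry.hessian_from_gradient(v)
        gns = detg - 1.0
        Ric = geometry.ricci_tensor(g_inv, H, gns)
        R = geometry.scalar_curvature(g_inv, H, gns)
        G = geometry.einstein_tensor(R, g, Ric)
        assert abs(R[c, c, c] - 6.0) < 1e-10
        assert np.abs(Ric[:, :, c, c, c] - 2.0 * np.eye(3)).max() < 1e-10
        assert np.abs(G[:, :, c, c, c] - 2.0 * np.eye(3)).max() < 1e-10

    def test_affine_level_set_is_flat_everywhere(self):
        n = 9
        x, y, z = np.indices((n, n, n), dtype=float)
        u = 0.3 * x - 1.2 * y + 0.7 * z + 4.0
        v = gradient_field(u)
        g, g_inv, detg = geometry.metric_from_gradient(v)
        H = geometry.hessian_from_gradient(v)
        gns = detg - 1.0
        R = geometry.scalar_curvature(g_inv, H, gns)
        Ric = geometry.ricci_tensor(g_inv, H, gns)
        # the Neumann faces of the gradient stencil perturb a 2-voxel rim
        m = (slice(2, -2),) * 3
        assert np.abs(R[m]).max() < 1e-10
        assert np.abs(Ric[(...,) + m]).max() < 1e-10


class TestRiemannComponent:
    def test_antisymmetry_and_pair_symmetry(self, rng):
        v = random_vector_field(rng)
        H = geometry.hessian_from_gradient(v)
        gns = geometry.grad_norm_sq(v)
        for i, k, j, l in [(1, 2, 1, 2), (1, 3, 2, 3), (2, 3, 1, 2)]:
            R_ikjl = geometry.riemann_component(H, gns, i, k, j, l)
            assert np.allclose(geometry.riemann_component(H, gns, k, i, j, l), -R_ikjl)
            assert np.allclose(geometry.riemann_component(H, gns, i, k, l, j), -R_ikjl)
            assert np.allclose(geometry.riemann_component(H, gns, j, l, i, k), R_ikjl)

    def test_invalid_index_rejected(self, rng):
        v = random_vector_field(rng)
        H = geometry.hessian_from_gradient(v)
        gns = geometry.grad_norm_sq(v)
        with pytest.raises(ValueError, match="1-based"):
            geometry.riemann_component(H, gns, 0, 1, 2, 3)
        with pytest.raises(ValueError, match="1-based"):
            geometry.riemann_component(H, gns, 1, 1, 2, 4)


class TestEnergy:
    def test_invariant_under_signed_axis_permutations(self):
        # Relabeling/reflecting the grid axes is an isometry of the graph
        # hypersurface, so the discrete total curvature must not change.
        rng = np.random.default_rng(7)
        from scipy import ndimage

        u = ndimage.gaussian_filter(rng.standard_normal((12, 14, 10)), 2.0)
        E0 = geometry.einstein_hilbert_energy(gradient_field(u))
        transforms = []
        for perm in ((0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0)):
            transforms.append(np.transpose(u, perm))
        for ax in range(3):
            transforms.append(np.flip(u, axis=ax))
        transforms.append(np.flip(np.transpose(u, (2, 0, 1)), axis=(0, 2)))
        for tu in transforms:
            E = geometry.einstein_hilbert_energy(gradient_field(np.ascontiguousarray(tu)))
            assert abs(E - E0) <= 1e-10 * max(1.0, abs(E0))

    def test_zero_for_constant_gradient(self):
        v = np.zeros((3, 8, 8, 8))
        v[0], v[1], v[2] = 2.0, -1.0, 0.5
        assert abs(geometry.einstein_hilbert_energy(v)) < 1e-12

    def test_voxel_volume_scaling(self, rng):
        v, h = band_limited_gradient(16, 3)
        E1 = geometry.einstein_hilbert_energy(v, (h, h, h))
        # same samples interpreted on a coarser grid: R scales as 1/h^2
        E2 = geometry.einstein_hilbert_energy(v, (2 * h, 2 * h, 2 * h))
        assert np.isfinite(E1) and np.isfinite(E2)
        assert not np.isclose(E1, E2)


class TestChristoffelOracle:
    def test_agrees_on_smooth_field(self):
        v, h = band_limited_gradient(24, 5)
        g, g_inv, detg = geometry.metric_from_gradient(v)
        H = geometry.hessian_from_gradient(v, (h, h, h))
        Ric = geometry.ricci_tensor(g_inv, H, detg - 1.0)
        Ric_oracle = geometry.ricci_oracle_christoffel(v, (h, h, h))
        m = (slice(2, -2),) * 3
        num = np.linalg.norm((Ric - Ric_oracle)[(...,) + m], axis=(0, 1))
        den = np.linalg.norm(Ric[(...,) + m], axis=(0, 1))
        assert np.median(num / (den + 1e-30)) < 0.05

    def test_zero_for_flat_field(self):
        v = np.zeros((3, 6, 6, 6))
        v[0] = 0.7  # constant gradient: flat graph
        Ric = geometry.ricci_oracle_christoffel(v)
        assert np.abs(Ric).max() < 1e-12

    def test_needs_five_voxels(self):
        with pytest.raises(ValueError, match=">= 5"):
            geometry.ricci_oracle_christoffel(np.zeros((3, 4, 6, 6)))
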
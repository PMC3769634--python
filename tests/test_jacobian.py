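"""Displacement fields, voxelization, harmonic interpolation, Jacobians."""

import numpy as np
import pytest

from hippomorph import (displacement_field, interpolate_heat,
                        jacobian_determinant, mesh_volume, project_to_surface,
                        volume_change_map, voxelize)


@pytest.fixture(scope="module")
def sphere_domain(sphere10):
    return voxelize(sphere10, spacing=1.0)


class TestDisplacementField:
    def test_identical_surfaces_zero(self, sphere10):
        d = displacement_field(sphere10, sphere10)
        assert np.abs(d.vectors).max() == 0
        assert np.abs(d.normal_component).max() == 0

    def test_radial_growth_normal_component(self, sphere10):
        grown = sphere10.copy_with(1.1 * sphere10.vertices)
        d = displacement_field(sphere10, grown)
        np.testing.assert_allclose(d.normal_component, 1.0, atol=1e-3)

    def test_translation_projects_on_normals(self, sphere10):
        shift = np.array([0.0, 0.0, 2.0])
        moved = sphere10.copy_with(sphere10.vertices + shift)
        d = displacement_field(sphere10, moved)
        np.testing.assert_allclose(d.vectors, np.broadcast_to(shift, d.vectors.shape), atol=1e-12)
        # normal component follows the cosine with the (radial) normal
        cos = sphere10.vertices[:, 2] / 10.0
        # tolerance set by the discrete normals' deviation from radial (~3e-3)
        np.testing.assert_allclose(d.normal_component, 2.0 * cos, atol=1e-2)


class TestVoxelize:
    def test_sphere_interior_count(self, sphere_domain):
        analytic = 4 * np.pi * 10 ** 3 / 3
        assert abs(sphere_domain.interior.sum() - analytic) < 0.05 * analytic

    def test_refinement_consistency(self, sphere10):
        fine = voxelize(sphere10, spacing=0.5)
        analytic = 4 * np.pi * 10 ** 3 / 3 / 0.125
        assert abs(fine.interior.sum() - analytic) < 0.02 * analytic

    def test_constant_field_assignment_exact(self, sphere_domain):
        c = np.array([1.0, -2.0, 3.0])
        vals = sphere_domain.assign_boundary(np.tile(c, (1002, 1)))
        np.testing.assert_allclose(vals, np.broadcast_to(c, vals.shape), atol=1e-12)

    def test_empty_interior_raises(self, sphere10):
        tiny = sphere10.copy_with(0.003 * sphere10.vertices + 0.5)
        with pytest.raises(ValueError, match="spacing"):
            voxelize(tiny, spacing=1.0)


class TestHeatInterpolation:
    def test_constant_boundary_reproduced(self, sphere_domain):
        c = np.array([2.0, 0.5, -1.0])
        n_b = int(sphere_domain.dirichlet.sum())
        field = interpolate_heat(sphere_domain, np.tile(c, (n_b, 1)))
        interior_vals = field.vectors[sphere_domain.interior]
        np.testing.assert_allclose(interior_vals, np.broadcast_to(c, interior_vals.shape), atol=1e-9)

    def test_linear_field_is_discrete_harmonic(self, sphere_domain):
        A = np.array([[0.05, 0.02, 0.0], [0.0, -0.03, 0.01], [0.02, 0.0, 0.04]])
        centers = sphere_domain.voxel_centers(
            np.argwhere(sphere_domain.dirichlet))
        field = interpolate_heat(sphere_domain, centers @ A.T)
        all_centers = sphere_domain.voxel_centers(
            np.argwhere(sphere_domain.domain_mask))
        expected = all_centers @ A.T
        got = field.vectors[sphere_domain.domain_mask]
        assert np.abs(got - expected).max() < 1e-6

    def test_discrete_maximum_principle(self, sphere_domain):
        rng = np.random.default_rng(7)
        n_b = int(sphere_domain.dirichlet.sum())
        for _ in range(5):
            b = rng.normal(size=(n_b, 1))
            field = interpolate_heat(sphere_domain, b)
            interior = field.vectors[sphere_domain.interior
                                     & ~sphere_domain.dirichlet]
            assert interior.min() >= b.min() - 1e-9
            assert interior.max() <= b.max() + 1e-9


class TestJacobian:
    def test_zero_displacement_gives_unity(self, sphere_domain):
        n_b = int(sphere_domain.dirichlet.sum())
        field = interpolate_heat(sphere_domain, np.zeros((n_b, 3)))
        J, valid = jacobian_determinant(field)
        assert np.all(J[valid] == 1.0)

    def test_translation_gives_unity(self, sphere_domain):
        n_b = int(sphere_domain.dirichlet.sum())
        field = interpolate_heat(sphere_domain,
                                 np.tile([3.0, -1.0, 2.0], (n_b, 1)))
        J, valid = jacobian_determinant(field)
        np.testing.assert_allclose(J[valid], 1.0, atol=1e-12)

    def test_uniform_scaling_analytic(self, sphere_domain):
        s = 1.1
        centers = sphere_domain.voxel_centers(
            np.argwhere(sphere_domain.dirichlet))
        field = interpolate_heat(sphere_domain, (s - 1) * centers)
        J, valid = jacobian_determinant(field)
        np.testing.assert_allclose(J[valid], s ** 3, atol=1e-3)

    def test_projection_of_scaling_case(self, sphere10, sphere_domain):
        s = 1.1
        centers = sphere_domain.voxel_centers(
            np.argwhere(sphere_domain.dirichlet))
        field = interpolate_heat(sphere_domain, (s - 1) * centers)
        J, valid = jacobian_determinant(field)
        jmap = project_to_surface(J, valid, sphere_domain, sphere10)
        assert np.abs(jmap.values - s ** 3).max() < 0.01 * s ** 3

    def test_projection_deterministic(self, sphere10, sphere_domain):
        n_b = int(sphere_domain.dirichlet.sum())
        rng = np.random.default_rng(0)
        b = rng.normal(scale=0.1, size=(n_b, 3))
        maps = []
        for _ in range(2):
            field = interpolate_heat(sphere_domain, b)
            J, valid = jacobian_determinant(field)
            maps.append(project_to_surface(J, valid, sphere_domain,
                                           sphere10).values)
        assert np.array_equal(maps[0], maps[1])


class TestFullChain:
    def test_growth_and_shrinkage_signs(self, tube):
        """Outward bump -> J - 1 > 0 at the bump; inward dent -> J - 1 < 0."""
        from hippomorph import BandEffect, EffectSpec, apply_effects
        _, _, surf = tube
        for mag, cmp in ((0.15, np.less), (-0.15, np.greater)):
            eff = EffectSpec(atrophy=BandEffect(magnitude=mag))
            deformed, truth = apply_effects(surf, eff, 0)
            jmap = volume_change_map(surf, deformed)
            core = truth["atrophy_weight"] > 0.99
            assert cmp(np.median(jmap.values[core] - 1.0), 0.0)

    def test_mean_jacobian_tracks_volume_change(self, tube):
        """Mean of (J-1) over the interior approximates the relative volume
        difference for a smooth synthetic deformation."""
        from hippomorph import BandEffect, EffectSpec, apply_effects
        from hippomorph.jacobian import (displacement_field,
                                         interpolate_heat,
                                         jacobian_determinant)
        _, _, surf = tube
        eff = EffectSpec(atrophy=BandEffect(magnitude=0.12))
        deformed, _ = apply_effects(surf, eff, 0)
        rel = mesh_volume(deformed) / mesh_volume(surf) - 1.0
        domain = voxelize(surf, 0.5)
        field = interpolate_heat(
            domain, domain.assign_boundary(
                displacement_field(surf, deformed).vectors))
        J, valid = jacobian_determinant(field)
        mean_change = float(np.mean(J[valid & domain.interior] - 1.0))
        assert abs(mean_change - rel) < 0.1 * abs(rel)

    def test_grid_refinement_reduces_error(self, sphere10):
        """Halving the spacing at least halves the worst-case error of the
        analytic uniform-scaling case measured at the surface."""
        s = 1.1
        errs = []
        for spacing in (2.0, 1.0):
            domain = voxelize(sphere10, spacing)
            centers = domain.voxel_centers(np.argwhere(domain.dirichlet))
            field = interpolate_heat(domain, (s - 1) * centers)
            J, valid = jacobian_determinant(field)
            jmap = project_to_surface(J, valid, domain, sphere10)
            errs.append(np.abs(jmap.values - s ** 3).max())
        assert errs[1] <= errs[0] / 2 + 1e-12
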
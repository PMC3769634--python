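"""Mean meridian axis: meridians, midpoints, strip, signed curvature."""

import numpy as np
import pytest

from hippomorph import (BendEffect, EffectSpec, ShapeSpec, StripMesh,
                        apply_effects, compute_memax, fit_spharm, make_shape,
                        memax_from_model, memax_open_mesh, position_vectors,
                        prime_meridians, strip_gaussian_curvature)
from hippomorph.memax import _lattice_faces


@pytest.fixture(scope="module")
def sphere5_model(sampling):
    from hippomorph import SphericalParamMesh
    V, F, th, ph = sampling
    return fit_spharm(SphericalParamMesh(5.0 * V, F, th, ph), 4)


def sphere_band_strip(r=5.0, K=50):
    """3-row strip lying ON a sphere (adjacent longitudes), for the
    curvature estimator; this is distinct from the (planar) MEMAX strip of
    a sphere."""
    thk = np.arange(1, K + 1) * np.pi / (K + 1)
    dphi = np.pi / (K + 1)
    def ring(phi0):
        return np.column_stack([r * np.sin(thk) * np.cos(phi0),
                                r * np.sin(thk) * np.sin(phi0),
                                r * np.cos(thk)])
    verts = np.concatenate([ring(dphi), ring(0.0), ring(-dphi)])
    return StripMesh(verts, _lattice_faces(K), K)


def saddle_strip(y0=0.1, h=0.05, K=50):
    """Strip on z = x^2 - y^2 with its central sample at (0, y0), laid out so
    the lattice normals point toward +z and the mean curvature there is
    strictly positive (the sign is undefined on the H = 0 symmetry locus)."""
    ys = y0 + h * np.arange(-(K // 2), K - (K // 2))
    rows = [np.column_stack([np.full(K, x), ys, x ** 2 - ys ** 2])
            for x in (-h, 0.0, h)]
    return StripMesh(np.concatenate(rows), _lattice_faces(K), K)


class TestMeridians:
    def test_sphere_meridians_mirror_across_polar_axis(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 50)
        th = mer.latitudes
        np.testing.assert_allclose(
            mer.upper, np.column_stack([5 * np.sin(th), 0 * th, 5 * np.cos(th)]),
            atol=1e-9)
        np.testing.assert_allclose(
            mer.lower, np.column_stack([-5 * np.sin(th), 0 * th, 5 * np.cos(th)]),
            atol=1e-9)

    def test_equiangular_latitudes(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 5)
        np.testing.assert_allclose(mer.latitudes, np.arange(1, 6) * np.pi / 6)

    def test_refit_round_trip_invariance(self, tube):
        from hippomorph import reconstruct_pdm
        _, model, _ = tube
        mer1 = prime_meridians(model, 30)
        refit = fit_spharm(reconstruct_pdm(model).as_param_mesh(),
                           model.max_degree)
        mer2 = prime_meridians(refit, 30)
        assert np.abs(mer1.upper - mer2.upper).max() < 1e-6

    def test_too_few_points_raises(self, sphere5_model):
        with pytest.raises(ValueError):
            prime_meridians(sphere5_model, 2)


class TestMemaxPoints:
    def test_sphere_memax_on_polar_axis(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 50)
        M = compute_memax(mer)
        assert np.abs(M[:, :2]).max() < 1e-9
        np.testing.assert_allclose(M[:, 2], 5 * np.cos(mer.latitudes),
                                   atol=1e-9)

    def test_degenerate_equal_meridians(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 10)
        mer.lower = mer.upper.copy()
        np.testing.assert_allclose(compute_memax(mer), mer.upper)

    def test_straight_tube_memax_collinear(self):
        model, _ = make_shape(ShapeSpec(bend_deg=0.0, taper=0.0))
        mx = memax_from_model(model, 50)
        off_axis = np.linalg.norm(mx.points[:, :2], axis=1)
        assert off_axis.max() < 1e-3 * 40.0

    def test_memax_rigid_equivariance(self, tube):
        from scipy.spatial.transform import Rotation
        _, model, surf = tube
        R = Rotation.from_euler("zyx", [20, -35, 10], degrees=True).as_matrix()
        t = np.array([3.0, -2.0, 5.0])
        moved = fit_spharm(surf.copy_with(surf.vertices @ R.T + t)
                           .as_param_mesh(), model.max_degree)
        a = compute_memax(prime_meridians(model, 40)) @ R.T + t
        b = compute_memax(prime_meridians(moved, 40))
        assert np.abs(a - b).max() < 1e-9

    def test_refining_k_keeps_coincident_latitudes(self, tube):
        _, model, _ = tube
        coarse = compute_memax(prime_meridians(model, 25))
        fine = compute_memax(prime_meridians(model, 51))
        # theta_k at K=25 equals theta_2k at K=51 (k pi/26 = 2k pi/52)
        np.testing.assert_allclose(coarse, fine[1::2], atol=1e-9)


class TestOpenMesh:
    def test_triangle_count(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 3)
        strip = memax_open_mesh(mer, compute_memax(mer))
        assert len(strip.faces) == 8  # 4(K-1)

    def test_planar_meridians_give_parallel_normals(self):
        K = 10
        x = np.linspace(0, 10, K)
        rows = [np.column_stack([x, np.full(K, y), np.zeros(K)])
                for y in (1.0, 0.0, -1.0)]
        strip = StripMesh(np.concatenate(rows), _lattice_faces(K), K)
        tri = strip.vertices[strip.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert np.abs(np.abs(n @ n[0]) - 1).max() < 1e-9

    def test_sphere_strip_in_xz_plane(self, sphere5_model):
        mer = prime_meridians(sphere5_model, 20)
        strip = memax_open_mesh(mer, compute_memax(mer))
        assert np.abs(strip.vertices[:, 1]).max() < 1e-9

    def test_self_intersection_warns(self):
        # middle row folded so the edge between its last two points pierces
        # the first upper-band triangle (which shares no vertex with it)
        K = 4
        up = np.array([[0.0, 1, 0], [1, 1, 0], [2, 1, 0], [3, 1, 0]])
        lo = np.array([[0.0, -1, 0], [1, -1, 0], [2, -1, 0], [3, -1, 0]])
        mid = np.array([[0.0, 0, 0], [1, 0, 0],
                        [0.5, 0.2, -0.5], [0.2, 0.9, 0.5]])
        from hippomorph.memax import Meridians
        mer = Meridians(np.linspace(0.5, 2.5, K), up, lo)
        with pytest.warns(RuntimeWarning, match="self-intersecting"):
            memax_open_mesh(mer, mid)


class TestCurvature:
    def test_sphere_band_curvature(self):
        strip = sphere_band_strip(r=5.0, K=50)
        kappa, valid = strip_gaussian_curvature(strip)
        inner = kappa[valid]
        assert np.abs(inner - 0.04).max() < 0.1 * 0.04

    def test_planar_strip_flat(self):
        K = 50
        x = np.linspace(0, 10, K)
        rows = [np.column_stack([x, np.full(K, y), np.zeros(K)])
                for y in (1.0, 0.0, -1.0)]
        strip = StripMesh(np.concatenate(rows), _lattice_faces(K), K)
        kappa, _ = strip_gaussian_curvature(strip)
        assert np.abs(kappa).max() < 1e-9

    def test_mirror_flips_every_sign_exactly(self):
        strip = sphere_band_strip()
        kappa, valid = strip_gaussian_curvature(strip)
        mirrored = StripMesh(strip.vertices * np.array([1.0, 1.0, -1.0]),
                             strip.faces, strip.K)
        kappa_m, valid_m = strip_gaussian_curvature(mirrored)
        assert np.array_equal(valid, valid_m)
        assert np.array_equal(kappa_m[valid], -kappa[valid])

    def test_saddle_central_point_negative(self):
        strip = saddle_strip(y0=0.1, h=0.05, K=50)
        kappa, valid = strip_gaussian_curvature(strip)
        center = kappa[strip.K // 2]
        assert center < 0
        assert abs(center - (-4.0)) < 0.15 * 4.0

    def test_bend_increases_curvature_monotonically(self):
        """Mean |kappa| over the bent segment grows with the ramp angle."""
        spec = ShapeSpec()
        _, surf = make_shape(spec)
        start = 2 * np.pi / 3
        means = []
        for ang in (5.0, 10.0, 20.0, 30.0):
            bent, _ = apply_effects(
                surf, EffectSpec(bend=BendEffect(start_lat=start,
                                                 angle_deg=ang)), 0)
            mx = memax_from_model(fit_spharm(bent.as_param_mesh(), 12), 50)
            seg = mx.latitudes >= start
            means.append(np.abs(mx.curvature[seg]).mean())
        assert np.all(np.diff(means) > 0)


class TestPositionVectors:
    def test_identical_is_zero(self, sphere5_model):
        M = compute_memax(prime_meridians(sphere5_model, 20))
        assert np.abs(position_vectors(M, M)).max() == 0

    def test_rigid_shift_recovered(self, sphere5_model):
        M = compute_memax(prime_meridians(sphere5_model, 20))
        d = position_vectors(M + [0.0, 2.0, 0.0], M)
        np.testing.assert_allclose(
            d, np.broadcast_to([0.0, 2.0, 0.0], d.shape), atol=1e-9)

    def test_bend_confined_to_posterior(self):
        """Analytic ground truth: a posterior bend leaves anterior MEMAX
        points untouched exactly."""
        from hippomorph import analytic_memax
        spec = ShapeSpec()
        K = 50
        lat = np.arange(1, K + 1) * np.pi / (K + 1)
        start = 2 * np.pi / 3
        base = analytic_memax(spec, None, K)
        bent = analytic_memax(
            spec, EffectSpec(bend=BendEffect(start_lat=start, angle_deg=20.0)),
            K)
        d = np.linalg.norm(position_vectors(bent, base), axis=1)
        assert d[lat < start - 1e-12].max() < 1e-6
        assert d[lat >= start].max() > 1.0

    def test_k_mismatch_raises(self, sphere5_model):
        M = compute_memax(prime_meridians(sphere5_model, 20))
        with pytest.raises(ValueError):
            position_vectors(M[:-1], M)
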
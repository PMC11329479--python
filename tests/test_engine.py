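import math

import numpy as np
import pytest

from gpse.core import MuellerImage, MuellerMatrix, normalize_mueller
from gpse.engine import (
    GPSEPointCloud,
    fit_gpse_ellipsoid,
    gpse_axis_orientation,
    gpse_from_mueller,
    gpse_map,
    gpse_parameters,
    gpse_point_cloud,
    optimal_incident_state,
    region_mean_mueller,
    sample_full_polarization_states,
)
from gpse.errors import InsufficientDataError, ParameterError, ProjectionError
from gpse.synth import (
    depolarizer_mueller,
    diattenuator_mueller,
    ensemble_fibrous_mueller,
    retarder_mueller,
    EnsembleTissueParams,
)


def quadric_oracle(pts):
    """Independent brute-force quadric solve: fit the general quadric with
    the trace-one normalization A + B + C = 1 by plain least squares, then
    extract center / semi-axes / axes by eigendecomposition.  Shares no
    code path with the package's fit."""
    x, y, z = np.asarray(pts).T
    # unknowns: A, B, D, E, F, G, H, I, J with C = 1 - A - B
    lhs = np.column_stack(
        [
            x * x - z * z,
            y * y - z * z,
            x * y,
            x * z,
            y * z,
            x,
            y,
            z,
            np.ones_like(x),
        ]
    )
    rhs = -z * z
    sol, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    A, B, D, E, F, G, H, I, J = sol
    C = 1.0 - A - B
    q = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    center = -0.5 * np.linalg.solve(q, [G, H, I])
    k = center @ q @ center - J
    w, vecs = np.linalg.eigh(q)
    semi = np.sqrt(k / w)
    order = np.argsort(semi)[::-1]
    return center, semi[order], vecs[:, order]


class TestSampling:
    def test_canonical6(self):
        states = sample_full_polarization_states(method="canonical6")
        dirs = {tuple(s.direction) for s in states}
        assert dirs == {
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        }
        labels = {s.label for s in states}
        assert labels == {"H", "V", "P", "M", "R", "L"}

    def test_fibonacci_near_uniform(self):
        states = sample_full_polarization_states(2000, "fibonacci")
        assert len(states) == 2000
        mean = np.stack([s.direction for s in states]).mean(axis=0)
        assert np.linalg.norm(mean) < 0.01

    @pytest.mark.parametrize("method", ["fibonacci", "latlong", "canonical6"])
    def test_unit_norm_and_latitude(self, method):
        states = sample_full_polarization_states(200, method)
        for s in states:
            assert np.linalg.norm(s.direction) == pytest.approx(1.0, abs=1e-12)
            assert s.latitude == pytest.approx(math.asin(np.clip(s.direction[2], -1, 1)))

    def test_too_few_states_rejected(self):
        with pytest.raises(ParameterError):
            sample_full_polarization_states(5)


class TestPointCloud:
    def test_identity_fixes_directions(self, identity):
        states = sample_full_polarization_states(method="canonical6")
        cloud = gpse_point_cloud(identity, states)
        for p, s in zip(cloud.points, states):
            assert np.allclose(p, s.direction)

    def test_isotropic_depolarizer_shrinks_sphere(self):
        p = 0.15
        states = sample_full_polarization_states(100)
        cloud = gpse_point_cloud(depolarizer_mueller(p, p, p), states)
        for pt, s in zip(cloud.points, states):
            assert np.allclose(pt, p * s.direction)

    def test_ideal_polarizer_collapses_to_point(self):
        states = sample_full_polarization_states(50)
        cloud = gpse_point_cloud(
            diattenuator_mueller(1.0, 0.0), states, check_physical=False
        )
        assert np.allclose(cloud.points, [1.0, 0.0, 0.0], atol=1e-12)

    def test_point_radius_is_output_dop(self, random_mueller_batch):
        from gpse.core import StokesVector, apply_mueller, degree_of_polarization

        (m,) = random_mueller_batch(1)
        states = sample_full_polarization_states(20)
        cloud = gpse_point_cloud(m, states)
        for r, s in zip(cloud.radii, states):
            dop = degree_of_polarization(apply_mueller(m, StokesVector(1, *s.direction)))
            assert r == pytest.approx(dop, abs=1e-12)

    def test_negative_intensity_raises(self):
        bad = np.eye(4)
        bad[0, 1] = -1.5  # S0' < 0 for the 0-deg state
        states = sample_full_polarization_states(method="canonical6")
        with pytest.raises(ProjectionError):
            gpse_point_cloud(MuellerMatrix(bad), states, check_physical=False)

    def test_empty_states_rejected(self, identity):
        with pytest.raises(ParameterError):
            gpse_point_cloud(identity, [])

    def test_unphysical_matrix_warns(self):
        m = MuellerMatrix(np.diag([1.0, 1.0, 1.0, -1.0]))
        with pytest.warns(UserWarning, match="physicality"):
            gpse_point_cloud(m, sample_full_polarization_states(10))


class TestEllipsoidFit:
    def test_unit_sphere(self, identity):
        _, ell, _ = gpse_from_mueller(identity)
        assert np.allclose(ell.center, 0, atol=1e-9)
        assert np.allclose(ell.semi_axes, 1, atol=1e-9)
        assert ell.fit_residual < 1e-10

    def test_spheroid_against_oracle(self):
        """Diattenuator(0.5) . isotropic depolarizer(0.5): the projected
        sphere satisfies (x - 0.4)^2 + 0.8 (y^2 + z^2) = 0.16 exactly."""
        m = MuellerMatrix(
            diattenuator_mueller(0.5, 0.0).m @ depolarizer_mueller(0.5, 0.5, 0.5).m
        )
        cloud, ell, params = gpse_from_mueller(m)
        assert np.allclose(ell.center, [0.4, 0, 0], atol=1e-6)
        assert np.allclose(ell.semi_axes, [0.44721360, 0.44721360, 0.4], atol=1e-6)
        c0, semi0, _ = quadric_oracle(cloud.points)
        assert np.allclose(ell.center, c0, atol=1e-6)
        assert np.allclose(ell.semi_axes, semi0, atol=1e-6)
        assert params.V == pytest.approx(0.43089, abs=1e-5)
        assert params.E == pytest.approx(0.31623, abs=1e-5)
        assert params.D_dagger == pytest.approx(0.92705, abs=1e-5)

    def test_random_matrices_against_oracle(self, random_mueller_batch):
        states = sample_full_polarization_states(800)
        for m in random_mueller_batch(10):
            cloud = gpse_point_cloud(m, states)
            ell = fit_gpse_ellipsoid(cloud)
            c0, semi0, _ = quadric_oracle(cloud.points)
            assert np.allclose(ell.center, c0, atol=1e-8)
            assert np.allclose(ell.semi_axes, semi0, atol=1e-8)

    def test_exact_quadric_residual(self, random_mueller_batch):
        states = sample_full_polarization_states(500)
        for m in random_mueller_batch(20):
            ell = fit_gpse_ellipsoid(gpse_point_cloud(m, states))
            assert ell.fit_residual < 1e-8

    def test_degenerate_polarizer(self):
        states = sample_full_polarization_states(50)
        cloud = gpse_point_cloud(
            diattenuator_mueller(1.0, 0.0), states, check_physical=False
        )
        ell = fit_gpse_ellipsoid(cloud)
        assert ell.degenerate
        assert np.allclose(ell.semi_axes, 0)
        assert np.allclose(ell.center, [1, 0, 0], atol=1e-12)

    def test_flat_ellipse_cloud(self):
        # one transmission channel fully blocked: the cloud fills a flat
        # ellipse; surviving semi-axes measured by half-extents are
        # accurate to the incident sampling density
        m = depolarizer_mueller(0.6, 0.3, 0.0)
        ell = fit_gpse_ellipsoid(gpse_point_cloud(m, sample_full_polarization_states(2000)))
        assert np.allclose(np.sort(ell.semi_axes), [0.0, 0.3, 0.6], atol=5e-3)
        assert ell.degenerate

    def test_segment_cloud(self):
        m = depolarizer_mueller(0.7, 0.0, 0.0)
        ell = fit_gpse_ellipsoid(gpse_point_cloud(m, sample_full_polarization_states(2000)))
        assert np.allclose(ell.semi_axes, [0.7, 0.0, 0.0], atol=5e-3)
        assert np.allclose(ell.center, 0.0, atol=5e-3)

    def test_too_few_points(self, identity):
        states = sample_full_polarization_states(method="canonical6")
        cloud = gpse_point_cloud(identity, states)
        with pytest.raises(InsufficientDataError):
            fit_gpse_ellipsoid(cloud)

    def test_orientation_is_proper_rotation(self, random_mueller_batch):
        states = sample_full_polarization_states(500)
        for m in random_mueller_batch(5):
            ell = fit_gpse_ellipsoid(gpse_point_cloud(m, states))
            r = ell.orientation
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_axes_order_and_containment(self, random_mueller_batch):
        states = sample_full_polarization_states(500)
        for m in random_mueller_batch(10):
            ell = fit_gpse_ellipsoid(gpse_point_cloud(m, states))
            a, b, c = ell.semi_axes
            assert a >= b >= c >= 0
            for k in range(3):
                tip = ell.center + ell.semi_axes[k] * ell.orientation[:, k]
                assert np.linalg.norm(tip) <= 1 + 1e-6
                tip = ell.center - ell.semi_axes[k] * ell.orientation[:, k]
                assert np.linalg.norm(tip) <= 1 + 1e-6


class TestParameters:
    def test_unit_sphere_limits(self):
        from gpse.engine import Ellipsoid

        e = Ellipsoid(np.zeros(3), np.ones(3), np.eye(3), 0.0)
        p = gpse_parameters(e)
        assert (p.V, p.E, p.D_dagger) == (1.0, 0.0, 0.0)
        assert not p.degenerate

    def test_hand_evaluated_prolate(self):
        from gpse.engine import Ellipsoid

        e = Ellipsoid(np.zeros(3), np.array([1.0, 0.5, 0.5]), np.eye(3), 0.0)
        p = gpse_parameters(e)
        assert p.V == pytest.approx(0.62996, abs=1e-5)
        assert p.E == pytest.approx(0.86603, abs=1e-5)
        assert p.D_dagger == 0.0

    def test_collapse_gives_nan_flags(self):
        from gpse.engine import Ellipsoid

        e = Ellipsoid(np.array([1.0, 0, 0]), np.zeros(3), np.eye(3), 0.0)
        p = gpse_parameters(e)
        assert p.V == 0.0
        assert math.isnan(p.E)
        assert math.isnan(p.D_dagger)
        assert p.degenerate

    def test_pure_retarder_is_unit_sphere(self):
        for delta, theta in [(0.7, 0.2), (2.5, -0.9), (math.pi, 0.0)]:
            _, _, p = gpse_from_mueller(retarder_mueller(delta, theta))
            assert p.V == pytest.approx(1.0, abs=1e-9)
            assert p.E == 0.0
            assert p.D_dagger == pytest.approx(0.0, abs=1e-9)

    def test_pure_diattenuator_is_unit_sphere(self):
        _, _, p = gpse_from_mueller(diattenuator_mueller(0.6, 0.4))
        assert p.V == pytest.approx(1.0, abs=1e-9)
        assert p.E == pytest.approx(0.0, abs=1e-6)
        assert p.D_dagger == pytest.approx(0.0, abs=1e-8)

    def test_anisotropic_depolarizer_sorted_axes(self):
        _, ell, p = gpse_from_mueller(depolarizer_mueller(0.6, 0.9, 0.7))
        assert np.allclose(ell.semi_axes, [0.9, 0.7, 0.6], atol=1e-9)
        assert p.V == pytest.approx(np.cbrt(0.6 * 0.9 * 0.7), abs=1e-9)

    def test_ranges(self, random_mueller_batch):
        for m in random_mueller_batch(20):
            _, _, p = gpse_from_mueller(m)
            assert 0.0 <= p.V <= 1.0 + 1e-9
            assert 0.0 <= p.E <= 1.0 + 1e-9
            assert p.D_dagger >= 0.0

    def test_retarder_rotation_equivariance(self, random_mueller_batch):
        """Post-composing with a pure retarder rotates the ellipsoid
        rigidly: V, E, D-dagger are invariant."""
        states = sample_full_polarization_states(500)
        (m,) = random_mueller_batch(1)
        _, _, p0 = gpse_from_mueller(m, states)
        ret = retarder_mueller(0.8, 0.3)
        _, _, p1 = gpse_from_mueller(MuellerMatrix(ret.m @ m.m), states)
        assert p1.V == pytest.approx(p0.V, abs=1e-9)
        assert p1.E == pytest.approx(p0.E, abs=1e-7)
        assert p1.D_dagger == pytest.approx(p0.D_dagger, abs=1e-9)

    def test_incident_rotation_invariance(self, random_mueller_batch):
        """Pre-rotating the incident sphere (a different uniform sampling)
        leaves the fitted ellipsoid unchanged."""
        (m,) = random_mueller_batch(1)
        s1 = sample_full_polarization_states(600)
        s2 = sample_full_polarization_states(601)
        _, e1, _ = gpse_from_mueller(m, s1)
        _, e2, _ = gpse_from_mueller(m, s2)
        assert np.allclose(e1.center, e2.center, atol=1e-9)
        assert np.allclose(e1.semi_axes, e2.semi_axes, atol=1e-9)


class TestAxisOrientation:
    def test_axis_aligned_spheroid(self):
        from gpse.engine import Ellipsoid

        e = Ellipsoid(np.zeros(3), np.array([1.0, 0.4, 0.4]), np.eye(3), 0.0)
        ang = gpse_axis_orientation(e)
        assert ang["defined"]
        assert ang["S1"] == pytest.approx(0.0, abs=1e-12)
        assert ang["S2"] == pytest.approx(math.pi / 2)

    def test_fiber_ensemble_long_axis_on_s1(self):
        m = ensemble_fibrous_mueller(
            EnsembleTissueParams(delta0=0.7, sigma_delta=0.5, theta0=0.0, p=1.0),
            mode="analytic",
        )
        _, ell, _ = gpse_from_mueller(m)
        ang = gpse_axis_orientation(ell)
        assert ang["defined"]
        assert ang["S1"] < 1e-6

    def test_rotated_triaxial_orientation(self):
        """A retarder about S1 rotates the middle/short axes in the S2-S3
        plane by its retardance."""
        base = depolarizer_mueller(0.9, 0.7, 0.6)
        rot = retarder_mueller(0.5, 0.0)  # rotates (S2,S3) by 0.5 rad
        _, e0, _ = gpse_from_mueller(base)
        _, e1, _ = gpse_from_mueller(MuellerMatrix(rot.m @ base.m))
        assert np.allclose(e1.semi_axes, e0.semi_axes, atol=1e-9)
        mid0, mid1 = e0.orientation[:, 1], e1.orientation[:, 1]
        cosang = abs(float(mid0 @ mid1))
        assert cosang == pytest.approx(abs(math.cos(0.5)), abs=1e-9)

    def test_sphere_orientation_undefined(self, identity):
        _, ell, _ = gpse_from_mueller(identity)
        ang = gpse_axis_orientation(ell)
        assert not ang["defined"]
        assert math.isnan(ang["S1"])


class TestRegionMean:
    def test_uniform_image(self, random_mueller_batch):
        (m,) = random_mueller_batch(1)
        img = MuellerImage(np.broadcast_to(m.m, (4, 5, 4, 4)).copy())
        mean = region_mean_mueller(img, np.ones((4, 5), bool))
        assert np.allclose(mean.m, m.m)

    def test_scaling_consistency(self, random_mueller_batch):
        (m,) = random_mueller_batch(1)
        img = MuellerImage(np.stack([np.stack([m.m, 3.0 * m.m])]))
        mean = region_mean_mueller(img, np.ones((1, 2), bool))
        assert np.allclose(mean.m, normalize_mueller(m).m)

    def test_empty_mask_rejected(self, identity):
        img = MuellerImage(np.broadcast_to(identity.m, (2, 2, 4, 4)).copy())
        with pytest.raises(ParameterError):
            region_mean_mueller(img, np.zeros((2, 2), bool))


class TestMap:
    def test_uniform_identity_image(self, identity):
        img = MuellerImage(np.broadcast_to(identity.m, (3, 3, 4, 4)).copy())
        maps = gpse_map(img, sample_full_polarization_states(200))
        assert np.allclose(maps["V"], 1.0, atol=1e-9)
        assert not maps["degenerate"].any()

    def test_single_pixel_matches_scalar_pipeline(self, random_mueller_batch):
        (m,) = random_mueller_batch(1)
        states = sample_full_polarization_states(300)
        img = MuellerImage(m.m[None, None])
        maps = gpse_map(img, states)
        _, _, p = gpse_from_mueller(m, states)
        assert maps["V"][0, 0] == pytest.approx(p.V, abs=1e-12)
        assert maps["E"][0, 0] == pytest.approx(p.E, abs=1e-12)
        assert maps["D_dagger"][0, 0] == pytest.approx(p.D_dagger, abs=1e-12)


class TestOptimalIncidentState:
    def test_equal_matrices_zero_distance(self, random_mueller_batch):
        (m,) = random_mueller_batch(1)
        _, dist, dists = optimal_incident_state(m, m)
        assert dist == 0.0
        assert np.allclose(dists, 0.0)

    def test_isotropic_pair_all_tie(self):
        p, q = 0.3, 0.8
        states = sample_full_polarization_states(100)
        best, dist, dists = optimal_incident_state(
            depolarizer_mueller(p, p, p), depolarizer_mueller(q, q, q), states
        )
        assert np.allclose(dists, abs(p - q), atol=1e-12)
        # tie-break: first state in the deterministic sampling order
        assert np.allclose(best.direction, states[0].direction)

    def test_fibrous_vs_isotropic_prefers_45deg_family(self):
        """A birefringent fibrous medium vs an isotropic depolarizer is
        best separated by states far from the 0/90-deg pair (which ride
        the fiber axis channels almost unchanged)."""
        iso = depolarizer_mueller(0.7, 0.7, 0.7)
        fib = ensemble_fibrous_mueller(
            EnsembleTissueParams(delta0=0.7, sigma_delta=0.3, p=0.9), mode="analytic"
        )
        states = sample_full_polarization_states(2000)
        best, dist, dists = optimal_incident_state(iso, fib, states)
        c6 = sample_full_polarization_states(method="canonical6")
        _, _, d6 = optimal_incident_state(iso, fib, c6)
        by_label = dict(zip([s.label for s in c6], d6))
        assert by_label["P"] > by_label["H"]
        assert by_label["M"] > by_label["V"]
        # the lattice optimum can undercut the exact canonical optimum only
        # by the sampling resolution
        assert dist >= max(d6) - 0.01
        assert abs(best.direction[0]) < 0.5  # optimum lies near S2-S3 circle
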
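"""Helical observables on fixtures with known ground truth."""

import math

import numpy as np
import pytest

from duplexcg import fixtures, geometry
from duplexcg.geometry import (
    CatmullRomSpline,
    DegenerateGeometryError,
    crookedness,
    fit_cylinder,
    force_axis_twist,
    h_rise,
    h_twist,
    helical_pitch,
    sbbs_dihedral,
    supercoiling_density,
    torsion_angle,
)


def rigid_motion(coords, seed=5):
    rng = np.random.default_rng(seed)
    axis = rng.normal(0, 1, 3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0.3, 2.5)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
    return coords @ R.T + rng.normal(0, 20, 3)


class TestCrookedness:
    def test_straight_line_is_zero(self):
        line = np.column_stack([np.zeros(12), np.zeros(12), np.arange(12.0)])
        beta, L = crookedness(line)
        assert beta == 0.0
        assert L == pytest.approx(11.0)

    def test_semicircle(self):
        t = np.linspace(0, math.pi, 2000)
        beta, _ = crookedness(np.column_stack([np.cos(t), np.sin(t), 0 * t]))
        assert beta == pytest.approx(math.acos(2 / math.pi), abs=1e-4)

    def test_coincident_centers_raise(self):
        pts = np.zeros((4, 3))
        with pytest.raises(DegenerateGeometryError):
            crookedness(pts)


class TestCylinderFit:
    def test_exact_cylinder(self):
        ang = np.linspace(0, 6 * math.pi, 50)
        pts = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang), np.linspace(0, 60, 50)])
        fit = fit_cylinder(pts, orient=[0, 0, 1])
        assert np.abs(fit.axis - [0, 0, 1]).max() < 1e-8
        assert fit.radius == pytest.approx(10.0, abs=1e-8)
        assert fit.rms_residual < 1e-8

    def test_rotation_equivariance(self):
        ang = np.linspace(0, 5 * math.pi, 40)
        pts = np.column_stack([7 * np.cos(ang), 7 * np.sin(ang), np.linspace(0, 40, 40)])
        moved = rigid_motion(pts, seed=8)
        fit0 = fit_cylinder(pts, orient=[0, 0, 1])
        fit1 = fit_cylinder(moved, orient=moved[-1] - moved[0])
        assert fit1.radius == pytest.approx(fit0.radius, abs=1e-8)

    def test_helix_fixture_radius(self, helix21):
        fit = geometry.helical_axis(helix21)
        assert fit.radius == pytest.approx(10.0, abs=1e-6)

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(10.0), [0, 0, 1.0])
        with pytest.raises(DegenerateGeometryError):
            fit_cylinder(pts)


class TestHelicalParameters:
    def test_ideal_helix_recovery(self, helix21):
        gamma, xi, zeta, p1, p2 = geometry.frame_points(helix21)
        fit = geometry.helical_axis(helix21)
        assert np.allclose(h_twist(zeta, fit.axis), 34.3, atol=1e-9)
        assert np.allclose(h_rise(xi, fit.axis), 3.4, atol=1e-9)

    def test_mirror_helix_negates_twist(self, helix21):
        mirrored = fixtures.ideal_helix_coords(helix21.sequence, rise=3.4,
                                               twist=34.3, radius=10.0, mirror=True)
        gamma, xi, zeta, p1, p2 = geometry.frame_points(mirrored)
        fit = geometry.helical_axis(mirrored)
        assert np.allclose(h_twist(zeta, fit.axis), -34.3, atol=1e-9)

    def test_axis_flip_flips_twist_and_rise(self, helix21):
        _, xi, zeta, _, _ = geometry.frame_points(helix21)
        axis = np.array([0.0, 0.0, 1.0])
        assert np.allclose(h_twist(zeta, -axis), -h_twist(zeta, axis))
        assert np.allclose(h_rise(xi, -axis), -h_rise(xi, axis))

    def test_rigid_motion_invariance(self, helix21):
        a0 = geometry.analyze_frame(helix21)
        a1 = geometry.analyze_frame(helix21, rigid_motion(helix21.coords))
        assert np.abs(a0.h_twist_deg - a1.h_twist_deg).max() < 1e-8
        assert np.abs(a0.h_rise_nm - a1.h_rise_nm).max() < 1e-8
        assert a1.beta == pytest.approx(a0.beta, abs=1e-8)
        assert a1.diameter_nm == pytest.approx(a0.diameter_nm, abs=1e-8)

    def test_zeta_parallel_to_axis_raises(self):
        zeta = np.tile([0.0, 0.0, 1.0], (5, 1))
        with pytest.raises(DegenerateGeometryError):
            h_twist(zeta, [0.0, 0.0, 1.0])


class TestForceAxisTwist:
    def test_matches_h_twist_for_z_aligned_helix(self, helix21):
        _, _, zeta, _, _ = geometry.frame_points(helix21)
        theta, psi = force_axis_twist(zeta)
        assert np.allclose(psi, 34.3, atol=1e-9)

    def test_cumulative_sum(self):
        helix = fixtures.ideal_helix_coords("ACGTACGTACG", twist=34.0)  # 10 steps
        _, _, zeta, _, _ = geometry.frame_points(helix)
        theta, _ = force_axis_twist(zeta)
        assert theta == pytest.approx(math.radians(340.0), abs=1e-9)

    def test_invariant_under_rotation_about_z(self, helix21):
        _, _, zeta, _, _ = geometry.frame_points(helix21)
        ang = 1.234
        R = np.array([[math.cos(ang), -math.sin(ang), 0],
                      [math.sin(ang), math.cos(ang), 0], [0, 0, 1]])
        theta0, _ = force_axis_twist(zeta)
        theta1, _ = force_axis_twist(zeta @ R.T)
        assert theta1 == pytest.approx(theta0, abs=1e-10)


class TestSbbsDihedral:
    def test_planar_cis_trans_and_quarter_turn(self):
        p = ([1, 0, 0], [0, 0, 0], [0, 0, 1])
        assert math.degrees(torsion_angle(*p, [1, 0, 1])) == pytest.approx(0.0)
        assert abs(math.degrees(torsion_angle(*p, [-1, 0, 1]))) == pytest.approx(180.0)
        assert math.degrees(torsion_angle(*p, [0, 1, 1])) == pytest.approx(90.0)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            torsion_angle([0, 0, 0], [0, 0, 1], [0, 0, 2], [1, 0, 3])

    def test_uniform_on_ideal_helix(self, helix21):
        vals = sbbs_dihedral(helix21)
        assert np.std(vals) < 1e-9


class TestScalars:
    def test_supercoiling_density(self):
        assert supercoiling_density(0.0, 10.0) == 0.0
        assert supercoiling_density(0.5, 10.0) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            supercoiling_density(1.0, 0.0)

    def test_helical_pitch(self):
        assert helical_pitch(np.full(99, 34.3)) == pytest.approx(360 / 34.3)
        assert helical_pitch(np.full(99, 68.6)) == pytest.approx(180 / 34.3)
        with pytest.raises(ValueError):
            helical_pitch(np.zeros(10))


class TestGrooves:
    def test_catmull_rom_interpolates_control_points(self):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(0, 1, (8, 3)), axis=0) + \
            np.outer(np.arange(8.0), [0, 0, 3.0])
        spline = CatmullRomSpline(pts)
        for i in range(1, 7):
            val = spline(np.array([spline.knots[i]]))[0]
            assert np.abs(val - pts[i]).max() < 1e-9

    def test_symmetric_duplex_has_equal_grooves(self):
        helix = fixtures.ideal_helix_coords(("ACGT" * 9), groove_phase=180.0)
        prof = geometry.groove_geometry(helix)
        sl = slice(4, 26)
        assert np.allclose(prof.minor_width[sl], prof.major_width[sl], atol=1e-5)

    def test_mirror_exchanges_major_minor(self):
        seq = ("ACGT" * 9)
        prof = geometry.groove_geometry(fixtures.ideal_helix_coords(seq))
        mirrored = geometry.groove_geometry(
            fixtures.ideal_helix_coords(seq, mirror=True))
        sl = slice(4, 26)
        assert np.allclose(mirrored.minor_width[sl], prof.major_width[sl], atol=1e-8)
        assert np.allclose(mirrored.major_width[sl], prof.minor_width[sl], atol=1e-8)

    def test_minor_groove_is_narrower_on_bdna_like_helix(self):
        prof = geometry.groove_geometry(fixtures.ideal_helix_coords("ACGT" * 9))
        sl = slice(4, 26)
        assert prof.minor_width[sl].mean() < prof.major_width[sl].mean()

    def test_uniform_along_ideal_helix(self):
        prof = geometry.groove_geometry(fixtures.ideal_helix_coords("ACGT" * 9))
        sl = slice(4, 26)
        assert np.std(prof.minor_width[sl]) < 1e-6
        assert np.std(prof.major_width[sl]) < 1e-6
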
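"""Schematic-eye assembly: corneal radii, stop ellipse, alpha, boundary points."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyepupil.eye import (
    ALPHA_AXIAL_MM,
    ALPHA_SR_SLOPE,
    CORNEAL_THICKNESS,
    DILATED_STOP_TILT,
    EyeSpec,
    alpha,
    build_eye,
    cornea_back_surface,
    cornea_front_radii,
    cornea_front_surface,
    iris_boundary_points,
    stop_boundary_points,
    stop_eccentricity,
    stop_geometry,
)
from eyepupil.optics import ConfigurationError


# ---------------------------------------------------------------------------
# Cornea
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sr, expected",
    [
        (0.0, (14.26, 10.43, 10.27)),
        (-5.0, (14.26 * 1.014, 10.43 * 1.014, 10.27 * 1.014)),
    ],
)
def test_front_radii_scale_linearly_with_ametropia(sr, expected):
    np.testing.assert_allclose(cornea_front_radii(sr), expected, rtol=1e-12)


def test_front_radii_guard_and_degenerate_root():
    with pytest.warns(UserWarning):
        cornea_front_radii(-25.0)
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            cornea_front_radii(1.0 / 0.0028)


def test_front_surface_apex_at_origin():
    surf = cornea_front_surface(0.0)
    assert abs(surf.implicit(np.zeros(3))) < 1e-12
    assert surf.center[0] == pytest.approx(14.26)


def test_back_surface_fixed_radii_and_apical_thickness():
    surf = cornea_back_surface(-7.0)  # independent of ametropia
    np.testing.assert_allclose(surf.radii, (13.7716, 9.3027, 9.3027))
    apex = np.array([CORNEAL_THICKNESS, 0.0, 0.0])
    assert abs(surf.implicit(apex)) < 1e-12
    assert surf.center[0] == pytest.approx(0.55 + 13.7716)


# ---------------------------------------------------------------------------
# Stop ellipse
# ---------------------------------------------------------------------------


def test_stop_eccentricity_sign_and_anchors():
    # Horizontal long axis (negative eps) when constricted, magnitude ~0.12.
    assert stop_eccentricity(0.05) < 0
    assert abs(stop_eccentricity(0.05)) == pytest.approx(0.12, abs=0.01)
    # Positive branch at the tanh midpoint and for dilated stops.
    assert stop_eccentricity(1.753) > 0
    assert stop_eccentricity(2.65) > 0
    # Saturation below the dilated entrance-pupil limit of 0.18.
    assert stop_eccentricity(10.0) < 0.18


def test_stop_tilt_branches():
    assert stop_geometry(0.5).theta == 0.0  # constricted: horizontal
    assert stop_geometry(2.65).theta == pytest.approx(DILATED_STOP_TILT)


def test_stop_shape_continuous_through_circular_crossover():
    r0 = 1.753 - math.atanh(0.099)  # eps = 0 exactly
    for r in (r0 - 1e-4, r0 + 1e-4):
        g = stop_geometry(r)
        assert g.semi_minor / g.semi_major == pytest.approx(1.0, abs=1e-6)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=0.5, max_value=4.0))
def test_stop_area_equals_equivalent_circle(r):
    g = stop_geometry(r)
    assert g.semi_major * g.semi_minor == pytest.approx(r * r, rel=1e-12)
    assert g.semi_minor / g.semi_major == pytest.approx(
        math.sqrt(1.0 - g.epsilon**2), rel=1e-12
    )


def test_circular_stop_when_elliptical_disabled():
    g = stop_geometry(2.65, elliptical=False)
    assert g.epsilon == 0.0 and g.semi_major == g.semi_minor == 2.65


# ---------------------------------------------------------------------------
# Alpha
# ---------------------------------------------------------------------------


def test_alpha_fixed_point_at_emmetropia():
    assert alpha(0.0, 5.5) == pytest.approx(5.5, abs=1e-12)
    assert alpha(0.0, 2.5) == pytest.approx(2.5, abs=1e-12)


def test_alpha_hand_evaluation_at_minus_10():
    expected = math.degrees(
        math.atan(
            ALPHA_AXIAL_MM
            / (ALPHA_AXIAL_MM - ALPHA_SR_SLOPE * (-10.0))
            * math.tan(math.radians(5.5))
        )
    )
    assert alpha(-10.0, 5.5) == pytest.approx(expected, abs=1e-12)
    assert alpha(-10.0, 5.5) == pytest.approx(4.66, abs=0.01)


def test_alpha_magnitude_shrinks_with_myopia():
    values = [alpha(sr, 5.5) for sr in (0.0, -2.0, -5.0, -10.0, -15.0)]
    assert all(a > b for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        alpha(ALPHA_AXIAL_MM / ALPHA_SR_SLOPE + 1.0, 5.5)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def test_all_flags_off_baseline():
    eye = build_eye(
        EyeSpec(corneal_refraction=False, alpha_enabled=False, elliptical_stop=False)
    )
    assert len(eye.optical_system.surfaces) == 0
    assert eye.stop.semi_major == eye.stop.semi_minor
    assert eye.alignment.alpha_horizontal == 0.0 == eye.alignment.alpha_vertical


def test_default_emmetrope_and_replication_eye():
    eye = build_eye(EyeSpec())
    front = eye.optical_system.surfaces[-1]
    np.testing.assert_allclose(front.radii, (14.26, 10.43, 10.27))
    rep = build_eye(EyeSpec(spherical_error=-0.823))
    np.testing.assert_allclose(
        rep.optical_system.surfaces[-1].radii,
        np.array([14.26, 10.43, 10.27]) * (1 + 0.0028 * 0.823),
    )
    assert rep.alignment.alpha_horizontal == pytest.approx(5.419, abs=0.01)
    assert rep.stop.center[0] == pytest.approx(3.9)


def test_stop_must_fit_inside_iris():
    with pytest.raises(ConfigurationError):
        build_eye(EyeSpec(stop_radius=5.6))


def test_boundary_points_on_stop_ellipse():
    eye = build_eye(EyeSpec(spherical_error=-0.823, stop_radius=2.65))
    pts = stop_boundary_points(eye, 16)
    assert pts.shape == (16, 3)
    g = eye.stop
    ct, st_ = math.cos(g.theta), math.sin(g.theta)
    for p in pts:
        assert p[0] == pytest.approx(3.9)
        u = (p[1]) * ct + (p[2]) * st_
        v = -(p[1]) * st_ + (p[2]) * ct
        assert (u / g.semi_major) ** 2 + (v / g.semi_minor) ** 2 == pytest.approx(
            1.0, abs=1e-12
        )


def test_boundary_point_count_validation():
    eye = build_eye(EyeSpec())
    with pytest.raises(ValueError):
        stop_boundary_points(eye, 4)
    circ = build_eye(EyeSpec(elliptical_stop=False, stop_radius=1.0))
    pts = stop_boundary_points(circ, 8)
    radii = np.linalg.norm(pts[:, 1:] - circ.stop.center[1:], axis=1)
    np.testing.assert_allclose(radii, 1.0, atol=1e-12)


def test_left_eye_is_mirror_of_right():
    right = build_eye(EyeSpec(spherical_error=-2.0, stop_radius=2.65))
    left = build_eye(EyeSpec(spherical_error=-2.0, stop_radius=2.65, laterality="left"))
    rp = stop_boundary_points(right, 16)
    lp = stop_boundary_points(left, 16)
    np.testing.assert_allclose(lp[:, 0], rp[:, 0], atol=1e-12)
    np.testing.assert_allclose(lp[:, 1], -rp[:, 1], atol=1e-12)  # horizontal flip
    np.testing.assert_allclose(lp[:, 2], rp[:, 2], atol=1e-12)


def test_iris_ring_is_circle_at_iris_depth():
    eye = build_eye(EyeSpec())
    pts = iris_boundary_points(eye, 12)
    assert np.allclose(pts[:, 0], 3.9)
    np.testing.assert_allclose(np.linalg.norm(pts[:, 1:], axis=1), 5.57, atol=1e-12)
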
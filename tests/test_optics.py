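"""Geometric-optics core: dispersion, quadric intersection, Snell refraction."""

import math

import numpy as np
import pytest

from eyepupil.config import make_fixture
from eyepupil.optics import (
    MEDIA,
    ConfigurationError,
    Medium,
    OpticalSystem,
    QuadricSurface,
    Ray,
    intersect_ray_quadric,
    refract,
    refractive_index,
    system_from_dict,
    system_to_dict,
    trace_through_system,
)


# ---------------------------------------------------------------------------
# Refractive index
# ---------------------------------------------------------------------------


def test_vacuum_limit_index_is_one():
    vac = Medium("vac", (1.0, 0.0, 0.0, 0.0))
    for lam in (400.0, 550.0, 800.0):
        assert refractive_index(vac, lam) == 1.0


@pytest.mark.parametrize(
    "name, lo, hi", [("aqueous", 1.33, 1.35), ("cornea", 1.37, 1.39)]
)
def test_ocular_media_indices_at_550(name, lo, hi):
    # Independent hand evaluation of the Cauchy series from the shipped table.
    a, b, c, d = MEDIA[name].cauchy
    lam = 0.550
    expected = a + b / lam**2 + c / lam**4 + d / lam**6
    n = refractive_index(name, 550.0)
    assert n == pytest.approx(expected, abs=1e-12)
    assert lo < n < hi


def test_index_physical_over_visible_range():
    lams = np.linspace(400.0, 800.0, 101)
    for name in ("air", "aqueous", "cornea"):
        n = np.array([refractive_index(name, l) for l in lams])
        assert np.all(n >= 1.0)
        assert np.all(np.diff(n) <= 1e-12)  # monotone non-increasing


def test_unknown_medium_is_configuration_error():
    with pytest.raises(ConfigurationError):
        refractive_index("vitreous_humour_typo", 550.0)


# ---------------------------------------------------------------------------
# Ray / quadric intersection
# ---------------------------------------------------------------------------


def _sphere(radius=10.0, side="any", **kw):
    return QuadricSurface(
        radii=(radius,) * 3, center=(0.0, 0.0, 0.0),
        medium_before="air", medium_after="air", side=side, **kw,
    )


def test_axis_aligned_sphere_hit():
    hit = intersect_ray_quadric(Ray([-20, 0, 0], [1, 0, 0]), _sphere(side="anterior"))
    assert hit is not None
    point, normal = hit
    np.testing.assert_allclose(point, [-10, 0, 0], atol=1e-12)
    np.testing.assert_allclose(normal, [-1, 0, 0], atol=1e-12)


def test_ray_from_sphere_center_exits_at_radius(rng):
    for _ in range(10):
        d = rng.normal(size=3)
        hit = intersect_ray_quadric(Ray([0, 0, 0], d), _sphere())
        assert hit is not None
        assert np.linalg.norm(hit[0]) == pytest.approx(10.0, abs=1e-10)


def test_miss_returns_none():
    assert intersect_ray_quadric(Ray([-20, 15, 0], [1, 0, 0]), _sphere()) is None
    # Backward-only intersection is not a forward hit.
    assert intersect_ray_quadric(Ray([-20, 0, 0], [-1, 0, 0]), _sphere()) is None


def test_intersection_satisfies_implicit_and_matrix_forms():
    surf = QuadricSurface(
        radii=(14.26, 10.43, 10.27), center=(14.26, 0, 0),
        medium_before="cornea", medium_after="air", side="anterior",
    )
    ray = Ray([3.9, 2.0, 1.0], [-0.9, 0.1, 0.05])
    point, normal = intersect_ray_quadric(ray, surf)
    assert abs(surf.implicit(point)) < 1e-9
    q = surf.implicit_matrix()
    xh = np.append(point, 1.0)
    assert abs(xh @ q @ xh) < 1e-9
    assert np.linalg.norm(normal) == pytest.approx(1.0, abs=1e-12)


def _bisection_march(ray, surf, t_max=500.0, step=0.1):
    """Independent oracle: march along the ray, bisect the first sign change."""
    f = lambda t: surf.implicit(ray.point_at(t))
    t_prev, f_prev = 1e-9, f(1e-9)
    t = t_prev + step
    while t <= t_max:
        ft = f(t)
        if f_prev * ft <= 0.0:
            lo, hi = t_prev, t
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0.0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)
        t_prev, f_prev = t, ft
        t += step
    return None


def test_closed_form_intersection_matches_bisection_oracle():
    bundle = make_fixture("quadric_rays", seed=2)
    checked = 0
    for radii, center, origin, direction in zip(
        bundle["radii"], bundle["centers"], bundle["origins"], bundle["directions"]
    ):
        surf = QuadricSurface(
            radii=tuple(radii), center=tuple(center),
            medium_before="air", medium_after="air", side="any",
        )
        ray = Ray(origin, direction)
        t_oracle = _bisection_march(ray, surf)
        hit = intersect_ray_quadric(ray, surf)
        if t_oracle is None:
            continue
        assert hit is not None
        assert np.linalg.norm(hit[0] - ray.point_at(t_oracle)) < 1e-6
        checked += 1
    assert checked >= 100


# ---------------------------------------------------------------------------
# Refraction
# ---------------------------------------------------------------------------


def test_normal_incidence_and_matched_media_leave_direction_unchanged(rng):
    for _ in range(5):
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        np.testing.assert_allclose(refract(-n, n, 1.0, 1.5), -n, atol=1e-12)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        np.testing.assert_allclose(refract(d, n, 1.42, 1.42), d, atol=1e-12)


def test_total_internal_reflection_beyond_critical_angle():
    # aqueous -> air, critical angle asin(1/1.336) ~ 48.5 deg
    n = np.array([-1.0, 0.0, 0.0])
    theta = math.radians(60.0)
    d = np.array([math.cos(theta), math.sin(theta), 0.0])
    assert refract(d, n, 1.336, 1.0) is None
    theta = math.radians(40.0)  # below critical: refracts
    d = np.array([math.cos(theta), math.sin(theta), 0.0])
    assert refract(d, n, 1.336, 1.0) is not None


def test_snell_ratio_planarity_reversibility(rng):
    checked = 0
    for _ in range(200):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        n1, n2 = rng.uniform(1.0, 1.8, size=2)
        t = refract(d, n, n1, n2)
        if t is None:
            continue
        cos_i = abs(d @ n)
        sin_i = math.sqrt(max(0.0, 1.0 - cos_i**2))
        cos_t = abs(t @ n)
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
        assert abs(n1 * sin_i - n2 * sin_t) < 1e-10  # Snell ratio
        assert abs(np.cross(d, n) @ t) < 1e-10  # coplanar
        back = refract(t, -n, n2, n1)
        assert back is not None
        np.testing.assert_allclose(back, d, atol=1e-10)  # reversibility
        assert np.linalg.norm(t) == pytest.approx(1.0, abs=1e-12)
        checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# Sequential tracing
# ---------------------------------------------------------------------------


def test_empty_system_is_identity():
    ray = Ray([3.9, 1.0, -0.5], [-1.0, 0.2, 0.1])
    path = trace_through_system(ray, OpticalSystem((), "air"))
    assert path.ok
    np.testing.assert_allclose(path.exit_ray.origin, ray.origin)
    np.testing.assert_allclose(path.exit_ray.direction, ray.direction)


def test_concentric_spheres_same_media_keep_direction():
    surfs = tuple(
        QuadricSurface(radii=(r,) * 3, center=(0, 0, 0),
                       medium_before="air", medium_after="air", side="anterior")
        for r in (20.0, 10.0)
    )
    ray = Ray([-50, 1.0, 2.0], [1.0, 0.0, 0.0])
    path = trace_through_system(ray, OpticalSystem(surfs, "air"))
    assert path.ok and len(path.points) == 2
    np.testing.assert_allclose(path.exit_ray.direction, ray.direction, atol=1e-12)


def test_axial_ray_through_cornea_stays_on_axis():
    from eyepupil.eye import cornea_back_surface, cornea_front_surface

    system = OpticalSystem(
        (cornea_back_surface(0.0), cornea_front_surface(0.0)), "aqueous"
    )
    path = trace_through_system(Ray([3.9, 0, 0], [-1, 0, 0]), system)
    assert path.ok
    np.testing.assert_allclose(path.exit_ray.direction, [-1, 0, 0], atol=1e-12)
    assert abs(path.exit_ray.origin[1]) < 1e-12 and abs(path.exit_ray.origin[2]) < 1e-12


def test_trace_failure_reports_surface_and_reason():
    sphere = _sphere(radius=5.0, side="anterior")
    path = trace_through_system(Ray([-20, 10, 0], [1, 0, 0]), OpticalSystem((sphere,), "air"))
    assert not path.ok
    assert path.failure.reason == "no_intersection" and path.failure.surface_index == 0

    # Steep exit from a dense sphere: TIR at the single surface.
    dense = QuadricSurface(radii=(5.0,) * 3, center=(0, 0, 0),
                           medium_before="aqueous", medium_after="air", side="any")
    theta = math.radians(80.0)
    origin = np.array([0.0, -4.9, 0.0])
    direction = np.array([math.sin(theta), math.cos(theta), 0.0])
    path = trace_through_system(Ray(origin, direction), OpticalSystem((dense,), "aqueous"))
    assert not path.ok and path.failure.reason == "tir"


def test_media_chain_validation():
    bad = (
        QuadricSurface(radii=(10,) * 3, center=(0, 0, 0),
                       medium_before="aqueous", medium_after="cornea"),
        QuadricSurface(radii=(11,) * 3, center=(0, 0, 0),
                       medium_before="air", medium_after="air"),
    )
    with pytest.raises(ConfigurationError):
        OpticalSystem(bad, "aqueous")


def test_system_serialization_round_trip():
    from eyepupil.eye import cornea_back_surface, cornea_front_surface

    system = OpticalSystem(
        (cornea_back_surface(0.0), cornea_front_surface(0.0)), "aqueous"
    )
    doc = system_to_dict(system)
    rebuilt = system_from_dict(doc)
    assert rebuilt.initial_medium == system.initial_medium
    for a, b in zip(system.surfaces, rebuilt.surfaces):
        np.testing.assert_allclose(a.radii, b.radii)
        np.testing.assert_allclose(a.center, b.center)
        assert a.medium_before == b.medium_before and a.side == b.side
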
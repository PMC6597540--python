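"""Geometric-optics core: quadric surfaces, skew-ray tracing, vector Snell refraction.

All geometry lives in a right-handed eye-world frame, in millimetres:

* axis 0 — axial depth, positive toward the retina (the corneal apex sits at 0),
* axis 1 — horizontal, positive toward the nasal visual field of a right eye,
* axis 2 — vertical, positive superior.

Surfaces are quadrics (here always axis-aligned ellipsoids) described by their
three semi-axis lengths, a centre, an orientation, which sheet of the quadric
is the optical surface, and an optional axial clip.  Refractive indices come
from a four-term Cauchy dispersion series per medium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Medium",
    "MEDIA",
    "refractive_index",
    "QuadricSurface",
    "Ray",
    "OpticalSystem",
    "TraceFailure",
    "TracedPath",
    "intersect_ray_quadric",
    "refract",
    "trace_through_system",
    "system_to_dict",
    "system_from_dict",
]

# Wavelength range over which the shipped dispersion tables are trusted (nm).
WAVELENGTH_RANGE_NM = (400.0, 800.0)
DEFAULT_WAVELENGTH_NM = 550.0


class ConfigurationError(ValueError):
    """Raised for inconsistent optical-system or media configuration."""


@dataclass(frozen=True)
class Medium:
    """A homogeneous optical medium with Cauchy dispersion.

    ``cauchy`` holds (A, B, C, D) with the wavelength expressed in micrometres:
    n(lam) = A + B/lam^2 + C/lam^4 + D/lam^6.
    """

    name: str
    cauchy: tuple[float, float, float, float]


# Coefficients fit exactly through published phase refractive indices of the
# ocular media at 458, 543.6, 589.3 and 632.8 nm (the standard four-line
# schematic-eye dispersion data).  Air is taken as exactly 1.
MEDIA: dict[str, Medium] = {
    "air": Medium("air", (1.0, 0.0, 0.0, 0.0)),
    "aqueous": Medium("aqueous", (1.31795172, 0.01224856, -0.00268086, 0.00026834)),
    "cornea": Medium("cornea", (1.36381289, 0.00582464, -0.00080661, 0.00008808)),
}


def get_medium(medium: Medium | str) -> Medium:
    if isinstance(medium, Medium):
        return medium
    try:
        return MEDIA[medium]
    except KeyError:
        raise ConfigurationError(f"unknown medium label: {medium!r}") from None


def refractive_index(medium: Medium | str, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> float:
    """Refractive index of ``medium`` at ``wavelength_nm`` via the Cauchy series."""
    med = get_medium(medium)
    lo, hi = WAVELENGTH_RANGE_NM
    if not (lo <= wavelength_nm <= hi):
        warnings.warn(
            f"wavelength {wavelength_nm} nm outside the calibrated range {lo}-{hi} nm",
            stacklevel=2,
        )
    lam = wavelength_nm / 1000.0  # micrometres
    a, b, c, d = med.cauchy
    inv2 = 1.0 / (lam * lam)
    return a + inv2 * (b + inv2 * (c + inv2 * d))


@dataclass(frozen=True)
class Ray:
    """A ray: origin (mm) and unit direction in eye-world coordinates."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        nrm = math.sqrt(float(d @ d))
        if not math.isfinite(nrm) or nrm == 0.0:
            raise ValueError("ray direction must be a nonzero finite vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / nrm)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class QuadricSurface:
    """One refractive boundary: an ellipsoidal quadric with media on each side.

    ``side`` selects the optical sheet along the local axial axis: "anterior"
    keeps intersections with local axial coordinate < 0 (the cap facing the
    camera), "posterior" the opposite cap, "any" disables the test.
    ``axial_max`` optionally clips the surface to world axial depth <= value
    (e.g. the cornea exists only anterior to the limbus).
    """

    radii: tuple[float, float, float]
    center: tuple[float, float, float]
    medium_before: str
    medium_after: str
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    side: str = "anterior"
    axial_max: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("quadric radii must all be positive")
        if self.side not in ("anterior", "posterior", "any"):
            raise ValueError(f"unknown side selector {self.side!r}")
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))

    # -- implicit form -----------------------------------------------------

    def implicit(self, point: np.ndarray) -> float:
        """Normalized implicit function f(x) = |R^T (x - c) / radii|^2 - 1."""
        local = self.orientation.T @ (np.asarray(point, dtype=float) - np.asarray(self.center))
        r = np.asarray(self.radii)
        return float(np.sum((local / r) ** 2) - 1.0)

    def implicit_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix Q with x^T Q x = 0 on the surface."""
        d = np.diag([1.0 / r**2 for r in self.radii])
        a = self.orientation @ d @ self.orientation.T
        c = np.asarray(self.center, dtype=float)
        q = np.empty((4, 4))
        q[:3, :3] = a
        q[:3, 3] = q[3, :3] = -a @ c
        q[3, 3] = c @ a @ c - 1.0
        return q

    def normal_at(self, point: np.ndarray) -> np.ndarray:
        """Unit outward normal (gradient of the implicit function)."""
        local = self.orientation.T @ (np.asarray(point, dtype=float) - np.asarray(self.center))
        grad_local = 2.0 * local / np.asarray(self.radii) ** 2
        grad = self.orientation @ grad_local
        return grad / math.sqrt(float(grad @ grad))


@dataclass(frozen=True)
class OpticalSystem:
    """Ordered refractive surfaces from the object side to the observer side."""

    surfaces: tuple[QuadricSurface, ...]
    initial_medium: str = "aqueous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "surfaces", tuple(self.surfaces))
        if self.surfaces and self.surfaces[0].medium_before != self.initial_medium:
            raise ConfigurationError(
                f"first surface starts in {self.surfaces[0].medium_before!r}, "
                f"system starts in {self.initial_medium!r}"
            )
        for a, b in zip(self.surfaces, self.surfaces[1:]):
            if a.medium_after != b.medium_before:
                raise ConfigurationError(
                    f"media chain broken between {a.name or a} and {b.name or b}"
                )


# ---------------------------------------------------------------------------
# Ray / quadric intersection
# ---------------------------------------------------------------------------

_MIN_T = 1e-9  # forward-progress guard, mm


def intersect_ray_quadric(
    ray: Ray, surface: QuadricSurface
) -> tuple[np.ndarray, np.ndarray] | None:
    """Nearest forward intersection of ``ray`` with the optical sheet of ``surface``.

    Returns ``(point, outward_unit_normal)`` or ``None`` when the ray misses
    the configured sheet/clip region.  Solved in closed form from the
    quadratic in the ray parameter.
    """
    center = np.asarray(surface.center, dtype=float)
    rot = surface.orientation
    o = rot.T @ (ray.origin - center)
    d = rot.T @ ray.direction
    inv_r2 = 1.0 / np.asarray(surface.radii) ** 2
    a = float(np.sum(d * d * inv_r2))
    b = 2.0 * float(np.sum(o * d * inv_r2))
    c = float(np.sum(o * o * inv_r2)) - 1.0
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    # Numerically stable quadratic roots.
    q = -0.5 * (b + math.copysign(sq, b))
    roots = sorted(t for t in (q / a, c / q if q != 0.0 else math.inf) if math.isfinite(t))
    for t in roots:
        if t <= _MIN_T:
            continue
        local = o + t * d
        if surface.side == "anterior" and local[0] >= 0.0:
            continue
        if surface.side == "posterior" and local[0] <= 0.0:
            continue
        point = ray.point_at(t)
        if surface.axial_max is not None and point[0] > surface.axial_max:
            continue
        return point, surface.normal_at(point)
    return None


# ---------------------------------------------------------------------------
# Refraction
# ---------------------------------------------------------------------------


def refract(
    direction: np.ndarray, normal: np.ndarray, n1: float, n2: float
) -> np.ndarray | None:
    """Vector Snell refraction of a unit ``direction`` across a unit ``normal``.

    The normal may point to either side; it is flipped internally to oppose
    the incident direction.  Returns the unit refracted direction, or ``None``
    on total internal reflection.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = -float(d @ n)
    if cos_i < 0.0:
        n = -n
        cos_i = -cos_i
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if k < 0.0:
        return None
    t = eta * d + (eta * cos_i - math.sqrt(k)) * n
    return t / math.sqrt(float(t @ t))


# ---------------------------------------------------------------------------
# Sequential tracing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceFailure:
    reason: str  # "no_intersection" | "tir"
    surface_index: int


@dataclass(frozen=True)
class TracedPath:
    points: tuple[np.ndarray, ...]  # intersection point on each surface, in order
    exit_ray: Ray
    failure: TraceFailure | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


def trace_through_system(
    ray: Ray, system: OpticalSystem, wavelength_nm: float = DEFAULT_WAVELENGTH_NM
) -> TracedPath:
    """Sequentially intersect and refract ``ray`` at every surface of ``system``.

    On failure the returned path records the surface index and whether the ray
    missed the surface or underwent total internal reflection; the points
    traced so far are preserved.
    """
    points: list[np.ndarray] = []
    current = ray
    for k, surf in enumerate(system.surfaces):
        hit = intersect_ray_quadric(current, surf)
        if hit is None:
            return TracedPath(tuple(points), current, TraceFailure("no_intersection", k))
        point, normal = hit
        n1 = refractive_index(surf.medium_before, wavelength_nm)
        n2 = refractive_index(surf.medium_after, wavelength_nm)
        new_dir = refract(current.direction, normal, n1, n2)
        if new_dir is None:
            points.append(point)
            return TracedPath(tuple(points), current, TraceFailure("tir", k))
        points.append(point)
        current = Ray(point, new_dir)
    return TracedPath(tuple(points), current, None)


# ---------------------------------------------------------------------------
# Serialization (documented schema, see docs/methods.md)
# ---------------------------------------------------------------------------


def system_to_dict(system: OpticalSystem) -> dict:
    return {
        "initial_medium": system.initial_medium,
        "surfaces": [
            {
                "name": s.name,
                "radii_mm": list(s.radii),
                "center_mm": list(s.center),
                "orientation": np.asarray(s.orientation).tolist(),
                "side": s.side,
                "axial_max_mm": s.axial_max,
                "medium_before": s.medium_before,
                "medium_after": s.medium_after,
            }
            for s in system.surfaces
        ],
        "media": {
            name: list(MEDIA[name].cauchy)
            for name in sorted(
                {system.initial_medium}
                | {s.medium_before for s in system.surfaces}
                | {s.medium_after for s in system.surfaces}
            )
            if name in MEDIA
        },
    }


def system_from_dict(doc: dict) -> OpticalSystem:
    for name, coeffs in doc.get("media", {}).items():
        MEDIA.setdefault(name, Medium(name, tuple(coeffs)))
    surfaces = [
        QuadricSurface(
            radii=tuple(s["radii_mm"]),
            center=tuple(s["center_mm"]),
            orientation=np.asarray(s.get("orientation", np.eye(3))),
            side=s.get("side", "anterior"),
            axial_max=s.get("axial_max_mm"),
            medium_before=s["medium_before"],
            medium_after=s["medium_after"],
            name=s.get("name", ""),
        )
        for s in doc.get("surfaces", [])
    ]
    return OpticalSystem(tuple(surfaces), doc.get("initial_medium", "aqueous"))
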
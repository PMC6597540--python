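"""Parameterized schematic eye: cornea, iris plane, elliptical aperture stop, axes.

The anterior segment is reduced to the parts a camera can see: a tri-axial
ellipsoidal cornea (front and back surfaces), a flat iris plane 3.9 mm behind
the corneal apex carrying an elliptical aperture stop centred on the optical
axis, and the misalignment angle alpha between the visual and optical axes.
Several components scale with the spherical refractive error SR (diopters,
negative = myopic):

* corneal front radii shrink linearly with SR (steeper cornea in myopia),
* alpha shrinks in magnitude as the eye elongates (more myopic),
* the stop ellipse transitions, via a tanh of stop radius, from a horizontal
  long axis when constricted through circular to a tilted vertical long axis
  when dilated.

All lengths in mm, angles in degrees except ellipse tilts (radians).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import ConfigurationError, OpticalSystem, QuadricSurface

__all__ = [
    "EyeSpec",
    "StopGeometry",
    "AxisAlignment",
    "EyeModel",
    "cornea_front_radii",
    "cornea_front_surface",
    "cornea_back_surface",
    "stop_eccentricity",
    "stop_geometry",
    "alpha",
    "build_eye",
    "stop_boundary_points",
    "iris_boundary_points",
]

# Emmetropic corneal front semi-axes (axial, horizontal, vertical), mm.
EMMETROPIC_FRONT_RADII = (14.26, 10.43, 10.27)
# Linear shrink of the front radii per diopter of spherical error.
FRONT_RADII_SR_SLOPE = 0.0028
# Corneal back semi-axes, independent of ametropia.
BACK_RADII = (13.7716, 9.3027, 9.3027)
# Corneal thickness at the apex, mm.
CORNEAL_THICKNESS = 0.55
# Stop-ellipse eccentricity model: eps(r) = EPS_SCALE*(tanh(r-EPS_CENTER)+EPS_OFFSET).
# The scale is the product 0.0303*4.760; see docs/methods.md for the grouping.
EPS_SCALE = 0.0303 * 4.760
EPS_CENTER = 1.753
EPS_OFFSET = 0.099
# Tilt of the stop ellipse when dilated (radians; vertical long axis, top
# leaning toward the nasal field).
DILATED_STOP_TILT = 3.0 * math.pi / 7.0
# Physical corneal rim (limbus) radius, mm — half the white-to-white
# diameter.  The corneal surfaces exist only anterior to this rim; rays that
# would exit beyond it have no valid path, which is what extinguishes
# boundary points at extreme viewing angles.
LIMBUS_RADIUS = 5.91
# Axial-length proxy in the alpha model: alpha = atan(16.5/(16.5-0.299 SR) tan(alpha0)).
ALPHA_AXIAL_MM = 16.5
ALPHA_SR_SLOPE = 0.299

SR_GUARD = (-20.0, 10.0)


@dataclass(frozen=True)
class EyeSpec:
    """Biometric parameters and feature flags for one model eye."""

    spherical_error: float = 0.0  # diopters; negative = myopic
    stop_radius: float = 3.0  # equivalent-area circle radius of the stop, mm
    alpha0_horizontal: float = 5.5  # deg, emmetropic visual-axis offset
    alpha0_vertical: float = 2.5  # deg
    iris_depth: float = 3.9  # mm posterior to the corneal apex
    iris_radius: float = 5.57  # mm, physical visible-iris ring
    laterality: str = "right"
    corneal_refraction: bool = True
    alpha_enabled: bool = True
    elliptical_stop: bool = True
    corneal_horizontal_radius: float | None = None  # override of front radius 2, mm
    wavelength_nm: float = 550.0

    def __post_init__(self) -> None:
        if self.stop_radius <= 0:
            raise ValueError("stop_radius must be positive")
        if self.laterality not in ("right", "left"):
            raise ConfigurationError(f"laterality must be right/left, got {self.laterality!r}")


@dataclass(frozen=True)
class StopGeometry:
    """The elliptical aperture stop in the iris plane."""

    epsilon: float  # signed non-linear eccentricity
    theta: float  # tilt of the long axis, radians (0 = horizontal)
    semi_major: float  # mm
    semi_minor: float  # mm
    center: np.ndarray  # 3-vector, on the optical axis at iris depth


@dataclass(frozen=True)
class AxisAlignment:
    """Angle between the visual and optical axes, degrees."""

    alpha_horizontal: float
    alpha_vertical: float


@dataclass(frozen=True)
class EyeModel:
    optical_system: OpticalSystem
    stop: StopGeometry
    alignment: AxisAlignment
    iris_radius: float
    spec: EyeSpec


# ---------------------------------------------------------------------------
# Component formulas
# ---------------------------------------------------------------------------


def _guard_sr(sr: float) -> None:
    lo, hi = SR_GUARD
    if not (lo <= sr <= hi):
        warnings.warn(
            f"spherical error {sr} D outside the plausible range [{lo}, {hi}] D",
            stacklevel=3,
        )


def cornea_front_radii(spherical_error: float) -> np.ndarray:
    """Corneal front-surface semi-axes (axial, horizontal, vertical) in mm."""
    _guard_sr(spherical_error)
    scale = 1.0 - FRONT_RADII_SR_SLOPE * spherical_error
    if scale <= 0.0:
        raise ValueError(f"degenerate cornea: scale factor {scale} for SR={spherical_error}")
    return np.asarray(EMMETROPIC_FRONT_RADII) * scale


def cornea_front_surface(
    spherical_error: float, horizontal_radius: float | None = None
) -> QuadricSurface:
    """Front corneal ellipsoid with its apex at depth 0 (cornea -> air)."""
    radii = cornea_front_radii(spherical_error)
    if horizontal_radius is not None:
        radii = radii.copy()
        radii[1] = horizontal_radius
    # Clip at the shallowest plane containing the limbus circle.
    r_min = float(min(radii[1], radii[2]))
    if LIMBUS_RADIUS < r_min:
        depth = float(radii[0]) * (1.0 - math.sqrt(1.0 - (LIMBUS_RADIUS / r_min) ** 2))
    else:
        depth = None
    return QuadricSurface(
        radii=tuple(radii),
        center=(float(radii[0]), 0.0, 0.0),
        medium_before="cornea",
        medium_after="air",
        side="anterior",
        axial_max=depth,
        name="cornea_front",
    )


def cornea_back_surface(spherical_error: float = 0.0, iris_depth: float = 3.9) -> QuadricSurface:
    """Back corneal ellipsoid, apex 0.55 mm behind the front apex (aqueous -> cornea).

    Clipped at the iris plane, where the cornea meets the iris root.
    """
    return QuadricSurface(
        radii=BACK_RADII,
        center=(CORNEAL_THICKNESS + BACK_RADII[0], 0.0, 0.0),
        medium_before="aqueous",
        medium_after="cornea",
        side="anterior",
        axial_max=iris_depth,
        name="cornea_back",
    )


def stop_eccentricity(stop_radius: float) -> float:
    """Signed non-linear eccentricity of the aperture-stop ellipse.

    Negative below the circular crossover (constricted pupils: horizontal long
    axis), positive above it (dilated pupils: near-vertical long axis).  A tanh
    of stop radius gives a smooth, saturating transition.
    """
    if stop_radius <= 0:
        raise ValueError("stop_radius must be positive")
    return EPS_SCALE * (math.tanh(stop_radius - EPS_CENTER) + EPS_OFFSET)


def stop_geometry(stop_radius: float, elliptical: bool = True, iris_depth: float = 3.9) -> StopGeometry:
    """Stop ellipse with the area of a circle of ``stop_radius``.

    Semi-axes a = r/(1-eps^2)^(1/4), b = r*(1-eps^2)^(1/4) so that
    a*b = r^2 and b/a = sqrt(1-eps^2); the magnitude of eps shapes the
    ellipse, its sign only selects the tilt branch.
    """
    eps = stop_eccentricity(stop_radius) if elliptical else 0.0
    theta = 0.0 if eps < 0 else DILATED_STOP_TILT
    if eps == 0.0:
        theta = 0.0
    q = (1.0 - eps * eps) ** 0.25
    return StopGeometry(
        epsilon=eps,
        theta=theta,
        semi_major=stop_radius / q,
        semi_minor=stop_radius * q,
        center=np.array([iris_depth, 0.0, 0.0]),
    )


def alpha(spherical_error: float, alpha0_deg: float) -> float:
    """Visual-axis offset (deg) at a given spherical error.

    The fovea sits a roughly fixed transverse distance from the optical axis
    while the eye elongates with myopia, so the angle shrinks as SR becomes
    more negative.
    """
    denom = ALPHA_AXIAL_MM - ALPHA_SR_SLOPE * spherical_error
    if denom <= 0:
        raise ValueError(f"alpha model undefined for SR={spherical_error}")
    return math.degrees(math.atan((ALPHA_AXIAL_MM / denom) * math.tan(math.radians(alpha0_deg))))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def build_eye(spec: EyeSpec) -> EyeModel:
    """Assemble the model eye described by ``spec``.

    The optical system is ordered from the object side outward: aqueous ->
    cornea back -> cornea front -> air.  With ``corneal_refraction`` off the
    system is empty and stop points are seen directly.  Left eyes are the
    mirror image of right eyes about the vertical (horizontal sign flipped).
    """
    if spec.corneal_refraction:
        system = OpticalSystem(
            (
                cornea_back_surface(spec.spherical_error, spec.iris_depth),
                cornea_front_surface(spec.spherical_error, spec.corneal_horizontal_radius),
            ),
            initial_medium="aqueous",
        )
    else:
        system = OpticalSystem((), initial_medium="air")

    stop = stop_geometry(spec.stop_radius, spec.elliptical_stop, spec.iris_depth)
    if stop.semi_major >= spec.iris_radius:
        raise ConfigurationError(
            f"stop semi-major axis {stop.semi_major:.2f} mm exceeds iris radius "
            f"{spec.iris_radius} mm"
        )

    if spec.alpha_enabled:
        align = AxisAlignment(
            alpha_horizontal=alpha(spec.spherical_error, spec.alpha0_horizontal),
            alpha_vertical=alpha(spec.spherical_error, spec.alpha0_vertical),
        )
    else:
        align = AxisAlignment(0.0, 0.0)

    return EyeModel(
        optical_system=system,
        stop=stop,
        alignment=align,
        iris_radius=spec.iris_radius,
        spec=spec,
    )


def _mirror_sign(eye: EyeModel) -> float:
    return -1.0 if eye.spec.laterality == "left" else 1.0


def stop_boundary_points(eye: EyeModel, n_points: int = 16) -> np.ndarray:
    """``n_points`` points on the stop ellipse at equal parameter angles.

    Five points uniquely determine an ellipse; fewer are rejected.  Points are
    returned as an (n, 3) array in the iris plane.
    """
    if n_points < 5:
        raise ValueError("at least 5 boundary points are required to define an ellipse")
    stop = eye.stop
    t = 2.0 * math.pi * np.arange(n_points) / n_points
    ct, st = math.cos(stop.theta), math.sin(stop.theta)
    u = stop.semi_major * np.cos(t)
    v = stop.semi_minor * np.sin(t)
    y = u * ct - v * st
    z = u * st + v * ct
    pts = np.column_stack([np.zeros(n_points), y * _mirror_sign(eye), z])
    return pts + stop.center


def iris_boundary_points(eye: EyeModel, n_points: int = 16) -> np.ndarray:
    """Points on the visible-iris ring (a circle in the iris plane)."""
    t = 2.0 * math.pi * np.arange(n_points) / n_points
    return np.column_stack(
        [
            np.full(n_points, eye.spec.iris_depth),
            eye.iris_radius * np.cos(t),
            eye.iris_radius * np.sin(t),
        ]
    )
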
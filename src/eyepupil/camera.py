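"""Pinhole camera, viewing-angle placement, and the inverse ray search.

The camera sits on an arc of fixed distance about the corneal apex.  The
viewing angle phi is measured in the horizontal plane relative to the line of
sight of the eye (negative = temporal visual field of a right eye); the
misalignment between the line of sight and the optical axis enters as a fixed
angular offset of the camera direction, so the eye itself stays axis-aligned
in world coordinates.

For every aperture-stop boundary point we search over the two departure
angles of a ray leaving that point for the ray that, after refraction by the
cornea, passes exactly through the camera pinhole.  The point where that ray
leaves the last optical surface is the virtual-image (entrance-pupil) point
seen by the camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .eye import EyeModel, stop_boundary_points
from .optics import OpticalSystem, Ray, TracedPath, trace_through_system

__all__ = [
    "CameraModel",
    "ViewGeometry",
    "VirtualImagePoint",
    "camera_aperture_position",
    "place_camera",
    "find_pinhole_ray",
    "entrance_pupil_center",
    "project_to_image",
    "image_stop_boundary",
]

DEFAULT_SOLVER_TOL_MM = 1e-4
DEFAULT_MAX_RESTARTS = 4

_WORLD_UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: intrinsics, optional radial distortion, and pose.

    ``rotation`` maps world vectors into the camera frame (rows = camera x, y,
    z axes; z is the boresight, x the image horizontal, y the image vertical).
    ``position`` is the pinhole aperture in world mm.  ``aim_point`` is the
    world point the boresight passes through (used to convert normalized image
    coordinates to mm in the object region).
    """

    intrinsics: np.ndarray = field(default_factory=lambda: np.eye(3))
    distortion: tuple[float, ...] = ()
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torsion: float = 0.0
    aim_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        k = np.asarray(self.intrinsics, dtype=float)
        if k[0, 0] <= 0 or k[1, 1] <= 0 or abs(k[1, 0]) > 0 or abs(k[2, 0]) > 0 or abs(k[2, 1]) > 0:
            raise ValueError("intrinsic matrix must be upper-triangular with positive focal terms")
        object.__setattr__(self, "intrinsics", k)
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "aim_point", np.asarray(self.aim_point, dtype=float))

    @property
    def aim_distance(self) -> float:
        return float(np.linalg.norm(self.aim_point - self.position))


@dataclass(frozen=True)
class ViewGeometry:
    """Camera placement on the viewing arc.

    ``offset_horizontal``/``offset_vertical`` carry the angular offset of the
    line of sight from the optical axis (the alpha angles); the aperture then
    sits along azimuth ``viewing_angle + offset_horizontal`` and elevation
    ``offset_vertical`` from the corneal apex.
    """

    viewing_angle: float  # deg; negative = temporal field of a right eye
    camera_distance: float = 100.0  # mm from the corneal apex
    offset_horizontal: float = 0.0  # deg
    offset_vertical: float = 0.0  # deg
    aim_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.camera_distance <= 0:
            raise ValueError("camera_distance must be positive")
        object.__setattr__(self, "aim_point", np.asarray(self.aim_point, dtype=float))


@dataclass(frozen=True)
class VirtualImagePoint:
    """Result of the pinhole-ray search for one stop boundary point."""

    world_point: np.ndarray | None  # on the last optical surface, mm
    source_stop_point: np.ndarray
    miss_distance: float
    status: str  # "found" | "tir" | "no_intersection" | "no_convergence"
    exit_ray: Ray | None = None
    departure_deg: tuple[float, float] | None = None  # (horizontal, vertical)

    @property
    def found(self) -> bool:
        return self.status == "found"


# ---------------------------------------------------------------------------
# Camera placement
# ---------------------------------------------------------------------------


def _arc_direction(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector from the apex toward the camera (out of the eye)."""
    h = math.radians(azimuth_deg)
    v = math.radians(elevation_deg)
    return np.array([-math.cos(v) * math.cos(h), math.cos(v) * math.sin(h), math.sin(v)])


def camera_aperture_position(view: ViewGeometry) -> np.ndarray:
    """Pinhole position on the viewing arc about the corneal apex."""
    u = _arc_direction(view.viewing_angle + view.offset_horizontal, view.offset_vertical)
    return view.camera_distance * u


def place_camera(
    view: ViewGeometry,
    intrinsics: np.ndarray | None = None,
    distortion: tuple[float, ...] = (),
    torsion: float = 0.0,
    centering: str = "translate",
) -> CameraModel:
    """Place the camera on the arc, centred on ``view.aim_point``.

    With ``centering="translate"`` (default) the boresight keeps the radial
    arc direction (toward the corneal apex) and the camera is shifted
    perpendicular to it until the boresight line passes through the aim
    point — the pupil stays centred in the image without tilting the image
    plane.  ``centering="reaim"`` instead keeps the aperture on the arc and
    rotates the boresight toward the aim point.
    """
    position = camera_aperture_position(view)
    if centering == "translate":
        z = -position / np.linalg.norm(position)
        w = view.aim_point - position
        position = position + (w - (w @ z) * z)
    elif centering == "reaim":
        z = view.aim_point - position
        z = z / np.linalg.norm(z)
    else:
        raise ValueError(f"unknown centering mode {centering!r}")
    x = np.cross(_WORLD_UP, z)
    nx = np.linalg.norm(x)
    if nx < 1e-12:  # boresight parallel to world up: pick horizontal image x
        x = np.array([0.0, 1.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    if torsion:
        ct, st = math.cos(math.radians(torsion)), math.sin(math.radians(torsion))
        x, y = ct * x + st * y, -st * x + ct * y
    rot = np.vstack([x, y, z])
    return CameraModel(
        intrinsics=np.eye(3) if intrinsics is None else intrinsics,
        distortion=tuple(distortion),
        rotation=rot,
        position=position,
        torsion=torsion,
        aim_point=view.aim_point,
    )


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def normalized_image_coords(world_point: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Perspective-divided (x, y) in the camera frame; error behind the camera."""
    pc = camera.rotation @ (np.asarray(world_point, dtype=float) - camera.position)
    if pc[2] <= 0:
        raise ValueError("point is behind the camera")
    xn, yn = pc[0] / pc[2], pc[1] / pc[2]
    if camera.distortion:
        r2 = xn * xn + yn * yn
        factor = 1.0
        p = r2
        for k in camera.distortion:
            factor += k * p
            p *= r2
        xn, yn = xn * factor, yn * factor
    return np.array([xn, yn])


def project_to_image(world_point: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project a world point to pixel coordinates."""
    xn, yn = normalized_image_coords(world_point, camera)
    k = camera.intrinsics
    return np.array([k[0, 0] * xn + k[0, 1] * yn + k[0, 2], k[1, 1] * yn + k[1, 2]])


def image_coords_mm(world_point: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Undistorted image coordinates scaled to mm at the aim-point distance.

    This expresses the apparent (entrance-pupil) geometry in world units in
    the plane through the aim point perpendicular to the boresight.
    """
    pc = camera.rotation @ (np.asarray(world_point, dtype=float) - camera.position)
    if pc[2] <= 0:
        raise ValueError("point is behind the camera")
    return np.array([pc[0] / pc[2], pc[1] / pc[2]]) * camera.aim_distance


# ---------------------------------------------------------------------------
# Inverse ray search
# ---------------------------------------------------------------------------


def _departure_direction(h: float, v: float) -> np.ndarray:
    """Unit departure direction from angles (radians) about the -axial axis."""
    return np.array([-math.cos(v) * math.cos(h), math.cos(v) * math.sin(h), math.sin(v)])


def _angles_from_direction(d: np.ndarray) -> tuple[float, float]:
    return math.atan2(d[1], -d[0]), math.asin(max(-1.0, min(1.0, d[2])))


def _miss_vector(path: TracedPath, aperture: np.ndarray) -> np.ndarray:
    """Perpendicular offset from the exit-ray line to the aperture point."""
    o, d = path.exit_ray.origin, path.exit_ray.direction
    w = aperture - o
    return w - (w @ d) * d


# Fixed restart offsets (radians) applied to the departure angles, tried in
# order of growing distance from the straight-line start so that the first
# converged solution is the one closest to the chief ray.
_RESTART_JITTERS = (
    (0.04, 0.0), (-0.04, 0.0), (0.0, 0.04), (0.0, -0.04),
    (0.08, 0.08), (-0.08, -0.08), (0.08, -0.08), (-0.08, 0.08),
)


def find_pinhole_ray(
    stop_point: np.ndarray,
    system: OpticalSystem,
    aperture: np.ndarray,
    wavelength_nm: float = 550.0,
    tol_mm: float = DEFAULT_SOLVER_TOL_MM,
    max_restarts: int = DEFAULT_MAX_RESTARTS,
) -> VirtualImagePoint:
    """Find the ray from ``stop_point`` that passes through the camera pinhole.

    A two-angle least-squares search over the departure direction, initialized
    at the straight line from the stop point to the aperture, minimizes the
    perpendicular miss of the traced exit ray at the pinhole.  On convergence
    (miss <= ``tol_mm``) the intersection of the solved ray with the last
    optical surface is returned as the virtual-image point.  A fixed sequence
    of jittered restarts is attempted before declaring the point missing, so
    the search is fully deterministic.
    """
    stop_point = np.asarray(stop_point, dtype=float)
    straight = aperture - stop_point
    straight = straight / np.linalg.norm(straight)

    if not system.surfaces:
        ray = Ray(stop_point, straight)
        h, v = _angles_from_direction(straight)
        return VirtualImagePoint(
            world_point=stop_point.copy(),
            source_stop_point=stop_point,
            miss_distance=0.0,
            status="found",
            exit_ray=ray,
            departure_deg=(math.degrees(h), math.degrees(v)),
        )

    failures: list[str] = []

    def residual(x: np.ndarray) -> np.ndarray:
        path = trace_through_system(
            Ray(stop_point, _departure_direction(x[0], x[1])), system, wavelength_nm
        )
        if not path.ok:
            failures.append(path.failure.reason)
            return np.full(3, 1e3)
        return _miss_vector(path, aperture)

    h0, v0 = _angles_from_direction(straight)
    x0 = np.array([h0, v0])

    best: tuple[float, np.ndarray] | None = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            start = x0
        else:
            jitter = _RESTART_JITTERS[(attempt - 1) % len(_RESTART_JITTERS)]
            start = x0 + np.asarray(jitter)
        try:
            sol = least_squares(residual, start, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:  # pragma: no cover - solver pathologies
            continue
        path = trace_through_system(
            Ray(stop_point, _departure_direction(*sol.x)), system, wavelength_nm
        )
        if not path.ok:
            continue
        miss = float(np.linalg.norm(_miss_vector(path, aperture)))
        if best is None or miss < best[0]:
            best = (miss, sol.x.copy())
        if miss <= tol_mm:
            break

    if best is not None and best[0] <= tol_mm:
        miss, x = best
        path = trace_through_system(
            Ray(stop_point, _departure_direction(*x)), system, wavelength_nm
        )
        return VirtualImagePoint(
            world_point=path.points[-1].copy(),
            source_stop_point=stop_point,
            miss_distance=miss,
            status="found",
            exit_ray=path.exit_ray,
            departure_deg=(math.degrees(x[0]), math.degrees(x[1])),
        )

    if failures:
        status = "tir" if failures.count("tir") >= failures.count("no_intersection") else "no_intersection"
    else:
        status = "no_convergence"
    return VirtualImagePoint(
        world_point=None,
        source_stop_point=stop_point,
        miss_distance=math.inf if best is None else best[0],
        status=status,
    )


def entrance_pupil_center(
    system: OpticalSystem,
    stop_center: np.ndarray,
    aperture: np.ndarray,
    wavelength_nm: float = 550.0,
    tol_mm: float = DEFAULT_SOLVER_TOL_MM,
) -> np.ndarray:
    """Virtual-image location of the stop centre as seen from ``aperture``.

    The chief ray from the stop centre to the pinhole is solved, then two
    neighbouring rays (small perturbations of the departure angles) are
    traced; the backward extensions of the three exit rays meet (in the
    least-squares sense) at the entrance-pupil centre.
    """
    stop_center = np.asarray(stop_center, dtype=float)
    if not system.surfaces:
        return stop_center.copy()
    chief = find_pinhole_ray(stop_center, system, aperture, wavelength_nm, tol_mm)
    if not chief.found:
        raise RuntimeError("could not solve the chief ray for the entrance-pupil centre")
    h0, v0 = (math.radians(a) for a in chief.departure_deg)
    delta = 1e-3
    lines = [chief.exit_ray]
    for dh, dv in ((delta, 0.0), (0.0, delta)):
        path = trace_through_system(
            Ray(stop_center, _departure_direction(h0 + dh, v0 + dv)), system, wavelength_nm
        )
        if path.ok:
            lines.append(path.exit_ray)
    if len(lines) < 2:
        raise RuntimeError("pencil tracing for the entrance-pupil centre failed")
    # Least-squares intersection point of the exit-ray lines.
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in lines:
        p = np.eye(3) - np.outer(ray.direction, ray.direction)
        a += p
        b += p @ ray.origin
    return np.linalg.solve(a, b)


# ---------------------------------------------------------------------------
# Imaging the stop boundary
# ---------------------------------------------------------------------------


def image_stop_boundary(
    eye: EyeModel,
    camera: CameraModel,
    n_points: int = 16,
    tol_mm: float = DEFAULT_SOLVER_TOL_MM,
    max_restarts: int = DEFAULT_MAX_RESTARTS,
    points: np.ndarray | None = None,
) -> list[dict]:
    """Image each stop boundary point through the cornea into the camera.

    Returns one record per boundary point with pixel and mm image coordinates
    (mm measured at the aim-point distance), the solver status and the miss
    distance.  With corneal refraction off the raw stop points are projected
    directly.  ``points`` overrides the stop boundary (e.g. the iris ring).
    """
    if points is None:
        points = stop_boundary_points(eye, n_points)
    system = eye.optical_system
    wl = eye.spec.wavelength_nm
    records = []
    for i, p in enumerate(points):
        vip = find_pinhole_ray(p, system, camera.position, wl, tol_mm, max_restarts)
        rec = {
            "point_index": i,
            "status": vip.status,
            "miss_mm": vip.miss_distance,
            "x_px": math.nan,
            "y_px": math.nan,
            "x_mm": math.nan,
            "y_mm": math.nan,
        }
        if vip.found:
            px = project_to_image(vip.world_point, camera)
            mm = image_coords_mm(vip.world_point, camera)
            rec.update(x_px=px[0], y_px=px[1], x_mm=mm[0], y_mm=mm[1])
        records.append(rec)
    return records
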
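"""Scripted simulations of entrance-pupil appearance.

These routines compose the schematic eye, the inverse ray search and the
pupil metrics into the standard numerical experiments:

* a horizontal sweep of camera viewing angles with the eye fixating through
  the camera at angle zero (the stationary-eye measurement geometry),
* calibration of the aperture-stop size against a requested on-axis
  entrance-pupil diameter (and of the iris ring against its imaged radius),
* an ablation suite that adds model components one at a time,
* sensitivity of the fitted cosine parameters to refractive error, stop
  size, iris depth and corneal width,
* boundary-quality profiles (missing points, ellipse-fit error) out to the
  angles where ray tracing fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .camera import (
    ViewGeometry,
    entrance_pupil_center,
    image_stop_boundary,
    place_camera,
)
from .eye import EyeModel, EyeSpec, build_eye, iris_boundary_points
from .metrics import (
    EllipseFitError,
    PdrFit,
    PupilObservation,
    fit_ellipse,
    fit_pdr_cosine,
    oblique_component,
    pdr,
    pdr_cosine,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "observe_pupil",
    "on_axis_observation",
    "calibrate_stop_to_entrance_diameter",
    "calibrate_iris_radius",
    "run_sweep",
    "ablation_suite",
    "turning_point_vs_sr",
    "e_sensitivity",
    "boundary_quality_profile",
    "REFERENCE_PDR_PARAMS",
]

DEFAULT_ANGLES = tuple(range(-75, 66, 5))
# Parameters of the published empirical cosine fit used as the fixed
# reference curve for ablation RMSE (D, beta in deg, E).
REFERENCE_PDR_PARAMS = (0.99, -5.30, 1.12)


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of a viewing-angle sweep."""

    eye: EyeSpec = field(default_factory=lambda: EyeSpec(spherical_error=-0.823))
    angles: tuple[float, ...] = DEFAULT_ANGLES
    camera_distance: float = 100.0  # mm
    n_points: int = 16
    entrance_pupil_diameter: float | None = 6.0  # mm; None = use eye.stop_radius as-is
    solver_tol_mm: float = 1e-4
    max_restarts: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(abs(a) > 90 for a in self.angles):
            raise ValueError("viewing angles must lie within [-90, 90] degrees")
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))


@dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame  # one row per viewing angle
    fit: PdrFit | None
    stop_radius: float  # mm, after any calibration
    miss_distances: np.ndarray  # all converged per-point miss distances, mm
    spec: SweepSpec


# ---------------------------------------------------------------------------
# Single observations
# ---------------------------------------------------------------------------


def _los_offsets(eye: EyeModel) -> tuple[float, float]:
    """Angular offset of the line of sight from the optical axis, degrees."""
    if not eye.spec.alpha_enabled:
        return 0.0, 0.0
    sign = -1.0 if eye.spec.laterality == "left" else 1.0
    return sign * eye.alignment.alpha_horizontal, eye.alignment.alpha_vertical


def observe_pupil(
    eye: EyeModel,
    viewing_angle: float,
    camera_distance: float = 100.0,
    n_points: int = 16,
    tol_mm: float = 1e-4,
    max_restarts: int = 4,
    los_offsets: tuple[float, float] | None = None,
) -> tuple[PupilObservation, list[dict]]:
    """Image the stop boundary from one viewing angle and fit the ellipse.

    The camera sits on the arc at ``viewing_angle`` relative to the line of
    sight and is aimed at the entrance-pupil centre.  Returns the observation
    (metrics computed on mm image coordinates) and the per-point records.
    """
    off_h, off_v = _los_offsets(eye) if los_offsets is None else los_offsets
    view = ViewGeometry(
        viewing_angle=viewing_angle,
        camera_distance=camera_distance,
        offset_horizontal=off_h,
        offset_vertical=off_v,
    )
    aperture = view.camera_distance * np.array(
        [
            -math.cos(math.radians(off_v)) * math.cos(math.radians(viewing_angle + off_h)),
            math.cos(math.radians(off_v)) * math.sin(math.radians(viewing_angle + off_h)),
            math.sin(math.radians(off_v)),
        ]
    )
    try:
        ep_center = entrance_pupil_center(
            eye.optical_system, eye.stop.center, aperture, eye.spec.wavelength_nm, tol_mm
        )
    except RuntimeError:
        # Even the chief ray has no valid path: the pupil is not visible at
        # this angle; report every boundary point as missing.
        obs = PupilObservation(viewing_angle, None, math.nan, math.nan, n_points, math.nan)
        return obs, []
    camera = place_camera(replace(view, aim_point=ep_center))
    records = image_stop_boundary(eye, camera, n_points, tol_mm, max_restarts)
    for rec in records:
        rec["angle"] = viewing_angle
    found = [r for r in records if r["status"] == "found"]
    n_missing = len(records) - len(found)
    if len(found) >= 5:
        try:
            ellipse, rmse = fit_ellipse(np.array([[r["x_mm"], r["y_mm"]] for r in found]))
            obs = PupilObservation(
                viewing_angle=viewing_angle,
                ellipse=ellipse,
                pdr=pdr(ellipse),
                oblique_c=oblique_component(ellipse),
                n_missing=n_missing,
                fit_rmse=rmse,
            )
            return obs, records
        except EllipseFitError:
            pass
    obs = PupilObservation(viewing_angle, None, math.nan, math.nan, n_missing, math.nan)
    return obs, records


def on_axis_observation(
    eye: EyeModel,
    camera_distance: float = 100.0,
    n_points: int = 16,
    tol_mm: float = 1e-4,
    points: np.ndarray | None = None,
) -> tuple[PupilObservation, list[dict]]:
    """Observation with the camera on the optical axis (alpha offsets ignored).

    ``points`` substitutes an arbitrary boundary (e.g. the visible-iris ring)
    for the stop boundary.
    """
    aperture = np.array([-camera_distance, 0.0, 0.0])
    ep_center = entrance_pupil_center(
        eye.optical_system, eye.stop.center, aperture, eye.spec.wavelength_nm, tol_mm
    )
    view = ViewGeometry(0.0, camera_distance, aim_point=ep_center)
    camera = place_camera(view)
    records = image_stop_boundary(eye, camera, n_points, tol_mm, points=points)
    found = [r for r in records if r["status"] == "found"]
    if len(found) < 5:
        raise RuntimeError("too few imaged points for an on-axis observation")
    ellipse, rmse = fit_ellipse(np.array([[r["x_mm"], r["y_mm"]] for r in found]))
    obs = PupilObservation(0.0, ellipse, pdr(ellipse), oblique_component(ellipse),
                           len(records) - len(found), rmse)
    return obs, records


# ---------------------------------------------------------------------------
# Calibrations against on-axis appearance
# ---------------------------------------------------------------------------


def _imaged_equivalent_diameter(spec: EyeSpec, stop_radius: float,
                                camera_distance: float, n_points: int = 16) -> float:
    eye = build_eye(replace(spec, stop_radius=stop_radius))
    obs, _ = on_axis_observation(eye, camera_distance, n_points)
    return 2.0 * math.sqrt(obs.ellipse.semi_major * obs.ellipse.semi_minor)


def calibrate_stop_to_entrance_diameter(
    spec: EyeSpec,
    target_diameter: float = 6.0,
    camera_distance: float = 100.0,
    n_points: int = 16,
    xtol: float = 1e-4,
) -> float:
    """Stop radius whose on-axis entrance pupil has ``target_diameter`` (mm).

    The entrance-pupil size is the equivalent-area diameter of the ellipse
    fit to the imaged stop boundary, expressed in mm at the entrance-pupil
    plane.  Without corneal refraction the stop is seen veridically and the
    radius is simply half the target.
    """
    if target_diameter <= 0:
        raise ValueError("target_diameter must be positive")
    if not spec.corneal_refraction:
        return target_diameter / 2.0
    lo, hi = 0.55 * target_diameter / 2.0, 1.05 * target_diameter / 2.0
    f = lambda r: _imaged_equivalent_diameter(spec, r, camera_distance, n_points) - target_diameter
    return float(brentq(f, lo, hi, xtol=xtol))


def calibrate_iris_radius(
    spec: EyeSpec,
    target_imaged_radius: float = 5.91,
    camera_distance: float = 100.0,
    n_points: int = 16,
    xtol: float = 1e-4,
) -> float:
    """Physical iris-ring radius whose on-axis imaged radius is the target (mm)."""

    def imaged(radius: float) -> float:
        eye = build_eye(replace(spec, iris_radius=radius))
        pts = iris_boundary_points(eye, n_points)
        obs, _ = on_axis_observation(eye, camera_distance, n_points, points=pts)
        return math.sqrt(obs.ellipse.semi_major * obs.ellipse.semi_minor)

    # Corneal magnification is >= 1 on axis, so the physical radius cannot
    # exceed its imaged radius.  Rings whose image falls beyond the corneal
    # rim are untraceable; back the upper bracket off until it traces.
    f = lambda r: imaged(r) - target_imaged_radius
    lo, hi = 0.85 * target_imaged_radius, target_imaged_radius
    while hi > lo:
        try:
            if f(hi) > 0:
                break
        except RuntimeError:
            pass
        hi -= 0.02 * target_imaged_radius
    else:
        raise RuntimeError("could not bracket the iris radius calibration")
    return float(brentq(f, lo, hi, xtol=xtol))


# ---------------------------------------------------------------------------
# The viewing-angle sweep
# ---------------------------------------------------------------------------


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the full viewing-angle sweep and fit the cosine summary.

    Builds the eye, calibrates the stop to the requested entrance-pupil
    diameter (when given), computes a :class:`PupilObservation` at every
    angle and fits PDR(phi) = D*cos((phi-beta)/E).
    """
    if spec.entrance_pupil_diameter is not None:
        stop_radius = calibrate_stop_to_entrance_diameter(
            spec.eye, spec.entrance_pupil_diameter, spec.camera_distance, spec.n_points
        )
    else:
        stop_radius = spec.eye.stop_radius
    eye = build_eye(replace(spec.eye, stop_radius=stop_radius))

    rows = []
    misses: list[float] = []
    for phi in spec.angles:
        obs, records = observe_pupil(
            eye,
            phi,
            spec.camera_distance,
            spec.n_points,
            spec.solver_tol_mm,
            spec.max_restarts,
        )
        misses.extend(r["miss_mm"] for r in records if r["status"] == "found")
        e = obs.ellipse
        rows.append(
            {
                "viewing_angle": phi,
                "pdr": obs.pdr,
                "tilt": e.tilt if e else math.nan,
                "oblique_c": obs.oblique_c,
                "semi_major_mm": e.semi_major if e else math.nan,
                "semi_minor_mm": e.semi_minor if e else math.nan,
                "center_x_mm": e.center[0] if e else math.nan,
                "center_y_mm": e.center[1] if e else math.nan,
                "n_missing": obs.n_missing,
                "fit_rmse_mm": obs.fit_rmse,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["pdr"])
    fit: PdrFit | None = None
    if len(valid) >= 4:
        fit = fit_pdr_cosine(valid["viewing_angle"].to_numpy(), valid["pdr"].to_numpy())
    return SweepResult(table, fit, stop_radius, np.asarray(misses), spec)


# ---------------------------------------------------------------------------
# Higher-level studies
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "A": dict(corneal_refraction=False, alpha_enabled=False, elliptical_stop=False),
    "B": dict(corneal_refraction=False, alpha_enabled=True, elliptical_stop=False),
    "C": dict(corneal_refraction=True, alpha_enabled=True, elliptical_stop=False),
    "D": dict(corneal_refraction=True, alpha_enabled=True, elliptical_stop=True),
}


def ablation_suite(base: SweepSpec) -> tuple[dict[str, SweepResult], pd.DataFrame]:
    """Re-run the sweep adding one model component at a time.

    Variant A: circular stop, no corneal refraction, optical axis = line of
    sight.  B adds the alpha misalignment, C corneal refraction, D the
    elliptical tilted stop.  The RMSE of each variant's PDR curve is computed
    against the fixed reference cosine with parameters
    ``REFERENCE_PDR_PARAMS`` evaluated at the sweep angles.
    """
    results: dict[str, SweepResult] = {}
    rows = []
    d0, b0, e0 = REFERENCE_PDR_PARAMS
    for label, flags in ABLATION_VARIANTS.items():
        spec = replace(base, eye=replace(base.eye, **flags))
        res = run_sweep(spec)
        results[label] = res
        valid = res.table.dropna(subset=["pdr"])
        ref = pdr_cosine(valid["viewing_angle"].to_numpy(), d0, b0, e0)
        rmse = float(np.sqrt(np.mean((valid["pdr"].to_numpy() - ref) ** 2)))
        rows.append({"variant": label, "rmse_vs_reference": rmse,
                     "beta_hat": res.fit.beta if res.fit else math.nan})
    return results, pd.DataFrame(rows)


def turning_point_vs_sr(sr_values, base: SweepSpec | None = None) -> pd.DataFrame:
    """Fitted turning point beta-hat as a function of spherical refractive error."""
    base = base or SweepSpec()
    rows = []
    for sr in sr_values:
        res = run_sweep(replace(base, eye=replace(base.eye, spherical_error=float(sr))))
        rows.append({"spherical_error": float(sr),
                     "beta_hat": res.fit.beta if res.fit else math.nan})
    return pd.DataFrame(rows)


def e_sensitivity(parameter: str, values, base: SweepSpec | None = None) -> pd.DataFrame:
    """Fitted half-period scale E-hat as one biometric parameter varies.

    ``parameter`` is one of ``stop_radius``, ``iris_depth`` or
    ``corneal_horizontal_radius``.  For ``stop_radius`` the entrance-pupil
    calibration is bypassed (the stop size itself is the variable); for the
    others the stop radius is held at the base calibrated value so that only
    the named parameter changes.
    """
    base = base or SweepSpec()
    if parameter not in ("stop_radius", "iris_depth", "corneal_horizontal_radius"):
        raise ValueError(f"unknown sensitivity parameter {parameter!r}")
    if parameter != "stop_radius" and base.entrance_pupil_diameter is not None:
        base_radius = calibrate_stop_to_entrance_diameter(
            base.eye, base.entrance_pupil_diameter, base.camera_distance, base.n_points
        )
        base = replace(
            base, eye=replace(base.eye, stop_radius=base_radius), entrance_pupil_diameter=None
        )
    rows = []
    for v in values:
        if parameter == "stop_radius":
            spec = replace(
                base, eye=replace(base.eye, stop_radius=float(v)), entrance_pupil_diameter=None
            )
        else:
            spec = replace(base, eye=replace(base.eye, **{parameter: float(v)}))
        res = run_sweep(spec)
        rows.append({parameter: float(v), "e_hat": res.fit.E if res.fit else math.nan})
    return pd.DataFrame(rows)


def boundary_quality_profile(
    spec: SweepSpec, angles=None
) -> pd.DataFrame:
    """Missing-point counts and ellipse-fit RMSE over an extended angle range."""
    if angles is None:
        angles = tuple(range(-85, 86, 5))
    extended = replace(spec, angles=tuple(float(a) for a in angles))
    res = run_sweep(extended)
    return res.table[["viewing_angle", "n_missing", "fit_rmse_mm"]].copy()
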
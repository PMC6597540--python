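"""Scalar descriptors of pupil appearance.

An ellipse is fit (direct least-squares conic fit) to the imaged boundary
points; the pupil diameter ratio (PDR) is the minor/major axis ratio of that
ellipse.  Across a horizontal sweep of viewing angles phi, PDR is summarized
by a decentered, flattened cosine

    PDR(phi) = D * cos((phi - beta) / E)

with the angles in degrees: D is the peak ratio, beta the viewing angle of
the peak (the turning point), and 180*E the half-period.  The oblique
component C = (1 - PDR) * sin(2*(theta - pi/2)) captures the tilt of the
pupil ellipse away from vertical, weighted by its ellipticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.measure import EllipseModel

__all__ = [
    "EllipseParams",
    "PupilObservation",
    "PdrFit",
    "EllipseFitError",
    "PdrFitError",
    "fit_ellipse",
    "pdr",
    "oblique_component",
    "pdr_cosine",
    "fit_pdr_cosine",
]


class EllipseFitError(RuntimeError):
    """The boundary points do not determine a valid ellipse."""


class PdrFitError(RuntimeError):
    """The cosine fit to the PDR curve did not converge."""


@dataclass(frozen=True)
class EllipseParams:
    """Fitted ellipse: centre, semi-axes (major >= minor) and tilt in [0, pi)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    tilt: float  # radians of the major axis from image horizontal


@dataclass(frozen=True)
class PupilObservation:
    """Per-viewing-angle summary of the imaged pupil."""

    viewing_angle: float  # deg
    ellipse: EllipseParams | None
    pdr: float
    oblique_c: float
    n_missing: int
    fit_rmse: float  # mm when the boundary points are in mm

    @property
    def valid(self) -> bool:
        return self.ellipse is not None


@dataclass(frozen=True)
class PdrFit:
    D: float
    beta: float  # deg
    E: float
    r_squared: float


# ---------------------------------------------------------------------------
# Ellipse fitting
# ---------------------------------------------------------------------------


def fit_ellipse(points: np.ndarray) -> tuple[EllipseParams, float]:
    """Direct least-squares ellipse fit with geometric-distance RMSE.

    ``points`` is (n, 2) with n >= 5.  The RMSE is the root mean squared
    orthogonal distance of the points from the fitted ellipse, in the units
    of the input.  Raises :class:`EllipseFitError` for degenerate input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError("at least 5 planar points are required")
    if not np.all(np.isfinite(pts)):
        raise EllipseFitError("non-finite boundary points")
    # Guard against rank-deficient (collinear) configurations.
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise EllipseFitError("ellipse fit failed (degenerate points)")
    with np.errstate(divide="ignore"):  # exact circles: tilt is indeterminate
        model = EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("ellipse fit failed (degenerate points)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if a <= 0 or b <= 0 or not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("ellipse fit returned a degenerate conic")
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    theta = theta % math.pi
    rmse = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return EllipseParams((float(xc), float(yc)), float(a), float(b), float(theta)), rmse


def pdr(ellipse: EllipseParams) -> float:
    """Pupil diameter ratio: minor over major axis."""
    return ellipse.semi_minor / ellipse.semi_major


def oblique_component(ellipse: EllipseParams) -> float:
    """Tilt-weighted ellipticity C = (1 - PDR) * sin(2*(theta - pi/2))."""
    return (1.0 - pdr(ellipse)) * math.sin(2.0 * (ellipse.tilt - math.pi / 2.0))


# ---------------------------------------------------------------------------
# Cosine summary of the PDR curve
# ---------------------------------------------------------------------------


def pdr_cosine(angles_deg: np.ndarray, d: float, beta: float, e: float) -> np.ndarray:
    """The decentered flattened cosine PDR(phi) = D*cos((phi-beta)/E), degrees."""
    return d * np.cos(np.radians((np.asarray(angles_deg, dtype=float) - beta) / e))


_FIT_START = (1.0, -5.0, 1.1)
_FIT_BOUNDS = ([0.5, -20.0, 0.8], [1.05, 20.0, 1.5])


def fit_pdr_cosine(angles_deg: np.ndarray, pdrs: np.ndarray) -> PdrFit:
    """Least-squares fit of the decentered flattened cosine to a PDR curve.

    Uses a single deterministic start (D=1, beta=-5, E=1.1) inside fixed
    bounds, so repeated fits of the same data are bit-identical.  R^2 is
    computed on the PDR values.  Raises :class:`PdrFitError` on failure.
    """
    phi = np.asarray(angles_deg, dtype=float)
    y = np.asarray(pdrs, dtype=float)
    mask = np.isfinite(phi) & np.isfinite(y)
    phi, y = phi[mask], y[mask]
    if len(np.unique(phi)) < 4:
        raise PdrFitError("need at least 4 distinct angles to fit the cosine")
    sol = least_squares(
        lambda p: pdr_cosine(phi, *p) - y,
        x0=np.array(_FIT_START),
        bounds=_FIT_BOUNDS,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise PdrFitError(f"cosine fit did not converge: {sol.message}")
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return PdrFit(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]), r2)
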
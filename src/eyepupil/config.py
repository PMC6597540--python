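"""Run configuration (YAML), result serialization and test-fixture generation.

The configuration schema mirrors the library's dataclasses block by block:
``eye`` (biometrics and feature flags), ``camera`` (intrinsics, distance),
``sweep`` (angles, boundary points, entrance-pupil diameter), ``solver``
(tolerance, restarts, seed) and ``output``.  An empty file yields the
default replication settings: SR = −0.823 D, 6 mm entrance pupil, camera at
100 mm, 16 boundary points, 550 nm, solver tolerance 1e−4 mm.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .eye import EyeSpec
from .experiments import SweepSpec
from .metrics import pdr_cosine

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_hash",
    "make_fixture",
]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the fields."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EyeBlock(_Block):
    spherical_error: float = -0.823
    stop_radius: float = Field(3.0, gt=0)
    alpha0_horizontal: float = 5.5
    alpha0_vertical: float = 2.5
    iris_depth: float = Field(3.9, gt=0)
    iris_radius: float = Field(5.57, gt=0)
    laterality: str = Field("right", pattern="^(right|left)$")
    corneal_refraction: bool = True
    alpha_enabled: bool = True
    elliptical_stop: bool = True
    corneal_horizontal_radius: float | None = Field(None, gt=0)
    wavelength_nm: float = Field(550.0, ge=400.0, le=800.0)


class CameraBlock(_Block):
    distance_mm: float = Field(100.0, gt=0)
    intrinsics: list[list[float]] | None = None  # row-major 3x3; None = ideal
    distortion: list[float] = Field(default_factory=list)
    torsion_deg: float = 0.0


class SweepBlock(_Block):
    angle_start: float = -75.0
    angle_stop: float = 65.0
    angle_step: float = Field(5.0, gt=0)
    n_points: int = Field(16, ge=5)
    entrance_pupil_diameter: float | None = Field(6.0, gt=0)

    def angles(self) -> tuple[float, ...]:
        n = int(round((self.angle_stop - self.angle_start) / self.angle_step)) + 1
        return tuple(self.angle_start + i * self.angle_step for i in range(n))


class SolverBlock(_Block):
    tolerance_mm: float = Field(1e-4, gt=0)
    max_restarts: int = Field(4, ge=0)
    seed: int = 0


class OutputBlock(_Block):
    directory: str = "."
    csv_name: str = "observations.csv"
    json_name: str = "summary.json"


class RunConfig(_Block):
    version: int = CONFIG_VERSION
    eye: EyeBlock = Field(default_factory=EyeBlock)
    camera: CameraBlock = Field(default_factory=CameraBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    # -- conversions to the library dataclasses ---------------------------

    def eye_spec(self) -> EyeSpec:
        e = self.eye
        return EyeSpec(
            spherical_error=e.spherical_error,
            stop_radius=e.stop_radius,
            alpha0_horizontal=e.alpha0_horizontal,
            alpha0_vertical=e.alpha0_vertical,
            iris_depth=e.iris_depth,
            iris_radius=e.iris_radius,
            laterality=e.laterality,
            corneal_refraction=e.corneal_refraction,
            alpha_enabled=e.alpha_enabled,
            elliptical_stop=e.elliptical_stop,
            corneal_horizontal_radius=e.corneal_horizontal_radius,
            wavelength_nm=e.wavelength_nm,
        )

    def sweep_spec(self) -> SweepSpec:
        return SweepSpec(
            eye=self.eye_spec(),
            angles=self.sweep.angles(),
            camera_distance=self.camera.distance_mm,
            n_points=self.sweep.n_points,
            entrance_pupil_diameter=self.sweep.entrance_pupil_diameter,
            solver_tol_mm=self.solver.tolerance_mm,
            max_restarts=self.solver.max_restarts,
            seed=self.solver.seed,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file = defaults.

    Validation failures raise :class:`ConfigError` whose message lists the
    offending field paths.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from None


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a config, for logging and provenance."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Deterministic test fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, seed: int = 0) -> dict:
    """Seeded input bundles for tests and the command line.

    Kinds:
      ``ellipse_points``  — 16 points on a random ellipse plus isotropic noise;
      ``quadric_rays``    — 100 random ray/ellipsoid pairs that intersect;
      ``pdr_curve``       — samples of the decentered flattened cosine with
                            sigma = 0.005 observation noise.
    """
    rng = np.random.default_rng(seed)
    if kind == "ellipse_points":
        a = rng.uniform(2.0, 4.0)
        b = rng.uniform(1.0, a)
        theta = rng.uniform(0.0, math.pi)
        center = rng.uniform(-1.0, 1.0, size=2)
        sigma = 0.01
        t = 2.0 * math.pi * np.arange(16) / 16
        ct, st = math.cos(theta), math.sin(theta)
        x = center[0] + a * np.cos(t) * ct - b * np.sin(t) * st
        y = center[1] + a * np.cos(t) * st + b * np.sin(t) * ct
        noisy = np.column_stack([x, y]) + rng.normal(0.0, sigma, size=(16, 2))
        return {
            "kind": kind,
            "seed": seed,
            "params": {"center": center, "semi_major": a, "semi_minor": b,
                       "theta": theta, "sigma": sigma},
            "points": noisy,
            "clean_points": np.column_stack([x, y]),
        }
    if kind == "quadric_rays":
        n = 100
        radii = rng.uniform(5.0, 15.0, size=(n, 3))
        centers = rng.uniform(-5.0, 5.0, size=(n, 3))
        # Rays aimed from outside toward a random interior point: always hit.
        interior = centers + rng.uniform(-0.3, 0.3, size=(n, 3)) * radii
        origins = centers + rng.normal(size=(n, 3)) * 30.0
        origins += np.sign(origins - centers) * radii  # push outside
        directions = interior - origins
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        return {"kind": kind, "seed": seed, "radii": radii, "centers": centers,
                "origins": origins, "directions": directions}
    if kind == "pdr_curve":
        d, beta, e = 0.99, -5.30, 1.12
        angles = np.arange(-75.0, 66.0, 5.0)
        sigma = 0.005
        pdrs = pdr_cosine(angles, d, beta, e) + rng.normal(0.0, sigma, size=angles.size)
        return {"kind": kind, "seed": seed, "angles": angles, "pdrs": pdrs,
                "params": {"D": d, "beta": beta, "E": e, "sigma": sigma}}
    raise ValueError(f"unknown fixture kind {kind!r}")
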
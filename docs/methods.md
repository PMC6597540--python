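# Methods

## Scope and coordinate conventions

The package models only what an external camera can see of the pupil: the
aqueous humor, the two corneal surfaces, the iris plane with its elliptical
aperture stop, and the visible iris ring.  The crystalline lens, vitreous
chamber and retina lie behind the stop and do not participate in the
imaging path of the entrance pupil; their only observable consequence —
the misalignment of the visual and optical axes — is modeled directly by
the angle α.  Reflective (Purkinje) paths, diffraction, polarization and
finite camera apertures are out of scope.

Coordinates are right-handed, in millimetres: axis 0 is the optical axis
(positive toward the retina, corneal apex at 0), axis 1 horizontal
(positive toward the nasal visual field of a right eye), axis 2 vertical
(positive superior).  Angles are degrees except ellipse tilts (radians).
Left eyes are mirror images of right eyes about the vertical plane.

## Optical surfaces and media

Each refracting surface is an axis-aligned ellipsoidal quadric described by
three semi-axis lengths, a centre, the sheet that forms the optical surface
(the anterior cap), and an axial clip.  Ray–surface intersection is solved
in closed form from the quadratic in the ray parameter, with the
numerically stable root formulation; surface normals are the unit gradient
of the implicit function.  Refraction uses the vector form of Snell's law
with re-normalized output; total internal reflection is reported as an
explicit failure, not an exception.

**Clipping.** The anterior cap of an ellipsoid extends far beyond the real
cornea, so both surfaces carry axial clips: the back surface ends at the
iris plane (the iris root), and the front surface at the shallowest plane
containing the limbus circle, with the physical corneal rim radius taken as
5.91 mm (half the mean white-to-white diameter).  This clip is what makes
stop boundary points disappear at extreme viewing angles: rays that would
have to exit beyond the rim have no valid path.  In this implementation
the loss of points begins just past −75° (temporal) and +65° (nasal) of
viewing angle, with the nasal side failing earlier because the line of
sight is rotated nasally relative to the optical axis.

**Dispersion.** Refractive indices come from a four-term Cauchy series per
medium, n(λ) = A + B/λ² + C/λ⁴ + D/λ⁶ with λ in µm.  The shipped
coefficients are fit exactly through published phase indices of the
ocular media at the four standard laser lines 458 / 543.6 / 589.3 /
632.8 nm, giving n(550 nm) = 1.3774 for the cornea and 1.3388 for the
aqueous; both series are ≥ 1 and monotone non-increasing over 400–800 nm.
Coefficients are overridable through the media table.  All simulations here
use 550 nm.

## The schematic eye

* Corneal front semi-axes `[14.26, 10.43, 10.27]·(1 − 0.0028·SR)` mm
  (axial, horizontal, vertical); apex at depth 0.  SR outside [−20, +10] D
  warns but computes, so sensitivity sweeps can run; the degenerate root of
  the scale factor raises.
* Corneal back semi-axes `[13.7716, 9.3027, 9.3027]` mm, independent of
  ametropia, apex at 0.55 mm.
* Stop eccentricity `ε(r) = 0.1442·(tanh(r − 1.753) + 0.099)`.  The leading
  constant is the product 0.0303·4.760; this grouping (rather than a
  leading 0.303, which would exceed |ε| = 1 for dilated stops) reproduces
  the anchor behaviours: ε ≈ −0.12 for small stops (horizontal long axis),
  a circular crossover at r ≈ 1.65 mm, and positive saturation at 0.159,
  below the 0.18 ceiling adopted for the dilated entrance pupil.  The tilt
  is 0 for ε < 0 and 3π/7 for ε > 0 (near-vertical, top toward the nasal
  field); |ε| shapes the ellipse, the sign only selects the branch.  The
  semi-axes a = r/(1−ε²)^¼, b = r·(1−ε²)^¼ preserve the equivalent-circle
  area πr² exactly.
* α(SR) = atan[(16.5/(16.5 − 0.299·SR))·tan α₀], applied independently to
  the horizontal (α₀ = 5.5°) and vertical (α₀ = 2.5°) components; the
  angle shrinks as the myopic eye elongates.
* The visible iris is a circle in the iris plane (radius 5.57 mm by
  default) imaged through the cornea exactly like stop points.

Feature flags (`corneal_refraction`, `alpha_enabled`, `elliptical_stop`)
remove one component at a time for the ablation study; with everything off
the imaged pupil is simply the perspective projection of a circle and its
PDR is the cosine of the viewing angle to better than 1e−3.

## Camera and the inverse ray search

The pinhole camera sits on an arc of fixed distance (default 100 mm) about
the corneal apex.  The viewing angle φ is measured in the horizontal plane
relative to the line of sight; the line-of-sight/optical-axis offset enters
as a fixed angular offset of the camera direction (azimuth φ + α_h,
elevation α_v), which is equivalent to rotating the eye so that it fixates
through the camera at φ = 0 — full foveal ray tracing is not needed for
this and is deliberately omitted.

**Centering.** At each angle the camera is *translated* perpendicular to a
radial boresight (pointing at the corneal apex) until the boresight line
passes through the entrance-pupil centre.  The alternative — keeping the
aperture on the arc and re-aiming the boresight — tilts the image plane by
up to ~2° at extreme angles and measurably flattens the fitted PDR curve
(Ê 1.17 vs 1.14); translation matches how the physical measurement is
described and is the default (`place_camera(..., centering="reaim")`
preserves the alternative).

**Inverse search.** For each stop boundary point the two departure angles
of the ray are found by Levenberg–Marquardt least squares on the
perpendicular miss vector between the traced exit ray and the pinhole,
initialized at the straight line from point to aperture.  Convergence is
declared at a miss ≤ 1e−4 mm (in practice the median converged miss is
~1e−14 mm).  If the first search fails, a fixed sequence of up to eight
jittered starts (±0.04–0.08 rad) is tried in order of growing distance
from the straight-line start, so the accepted solution is the one closest
to the chief ray and the whole pipeline is bit-for-bit deterministic; the
configured seed is recorded but no randomness remains in the solve path.
Points whose every candidate path fails are reported missing with the
dominant failure reason (TIR or no intersection).

**Virtual image and units.** The virtual-image location of a stop point is
the intersection of the solved ray with the last optical surface; since
the solved ray passes through the pinhole, any point along it projects to
the same image position.  The entrance-pupil *centre* is computed properly
as a virtual image: the chief ray from the stop centre is solved and two
neighbouring rays traced, and the least-squares meeting point of the
backward-extended exit rays is taken (about 3.3 mm behind the apex for the
default eye).  Image-plane quantities are expressed in mm by scaling the
normalized camera coordinates to the plane through the entrance-pupil
centre perpendicular to the boresight; PDR is scale-free, but ellipse-fit
RMSE and calibrated sizes depend on this convention, and with it both
printed magnification anchors are reproduced (5.3 mm stop ↔ 6 mm entrance
pupil; 5.57 mm iris ↔ 5.91 mm imaged).

## Pupil metrics

The imaged boundary is fit with the stable direct least-squares conic
(ellipse-constrained) fit; semi-axes are ordered major ≥ minor and the
tilt normalized to [0, π) from the image horizontal.  The fit RMSE is the
root-mean-square *geometric* (orthogonal) distance in mm; its numerical
floor is ~1e−8 even on exact data because the point-to-ellipse distance is
itself evaluated iteratively.  Fits need ≥ 5 non-degenerate points;
degenerate input raises a typed failure and the observation is marked
invalid.

PDR = minor/major.  The oblique component C = (1 − PDR)·sin[2(θ − π/2)]
vanishes for circles and for exactly vertical ellipses.  The cosine
summary PDR(φ) = D·cos[(φ − β)/E] is fit by bounded least squares
(D ∈ (0.5, 1.05), β ∈ (−20, 20)°, E ∈ (0.8, 1.5)) from the single
deterministic start (1, −5, 1.1); R² is computed on the PDR values
themselves (the natural scale; no transformation is applied).

## Experiments and default problem sizes

The default sweep covers −75…65° in 5° steps (29 angles — the published
grid is not stated; 5° resolves the fit comfortably) with 16 boundary
points per angle, and calibrates the stop radius by root-finding so the
on-axis entrance pupil has an equivalent-area diameter of 6 mm (result:
5.31 mm stop diameter).  The fixation distance of the original measurement
(3 m) affects only lens accommodation, which is out of scope; it is
metadata here.

Sensitivity studies vary one parameter per run while holding the stop at
its base calibrated size: stop radius over the physiological 1.5–3.5 mm
(Ê grows with stop size), iris depth by ±0.2 mm — the scale of
accommodative anterior-chamber shallowing — (Ê essentially flat,
range < 0.02), and the corneal horizontal semi-axis (a modest Ê change).
The ablation RMSE is computed against the fixed reference cosine
(D, β, E) = (0.99, −5.30, 1.12) evaluated at the sweep angles, so the
suite is self-contained.

## What the synthetic fixtures do and do not show

Test inputs are generated, not stored: random ellipsoid/ray pairs for the
intersection oracle (checked against an independent march-and-bisect
solver), noisy ellipse point sets, and noisy samples of the cosine law
(σ = 0.005).  These exercise the numerics under isotropic noise and exact
geometry; they do not emulate real eye images — no iris texture, no
specular reflections, no hand-marking bias, no corneal surface
irregularity — so passing tests demonstrate the forward model's internal
consistency and its agreement with the published *summary statistics*, not
performance on photographs.

## Known limitations

* Beyond about −75°/+65° the boundary is increasingly non-elliptical and
  points are lost; this implementation loses points somewhat faster than
  the reference ray tracer there, so beyond the limits the RMSE of the few
  surviving points can *drop* even as the boundary degrades.  Within the
  valid range RMSE stays below 0.02 mm and grows monotonically toward the
  limits.  The distorted far-peripheral pupil (limbus vignetting, non-
  ellipsoidal peripheral cornea, finite apertures) is not reconstructed.
* The stop is centred on the optical axis: nasal decentration of the
  pupil and its temporal shift with dilation are not modeled.
* One wavelength per run; no chromatic effects within a simulation.
* α follows a population-level trend with refractive error; individual
  variation about it is large and is not modeled.
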
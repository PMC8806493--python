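# Methods

`sbdot` monitors interstitial photothermal therapy (PTT) of the prostate with
continuous-wave (CW) transrectal diffuse optical tomography: an 8-source /
8-detector reflectance probe in the rectum measures 64 near-infrared
intensities per scan, and a shape-based inverse solver tracks the expanding
photocoagulation zone as an ellipsoid.  The safety-critical output is the
transverse distance between the coagulation boundary and the probe (rectal
wall).  This note records the model, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Forward model

Light transport is modeled by the CW diffusion approximation

    -∇·(D ∇Φ) + μa Φ = q,     D = 1 / (3 (μa + μs′)),

discretized by a cell-centered finite-volume scheme on a uniform structured
grid with harmonic averaging of D across voxel faces, which treats the sharp
property jump at the coagulation boundary conservatively.  The probe surface
(z = 0, planar half-space approximation of the 25 mm cylindrical probe) uses
a partial-current (Robin) boundary: outward flux per area Φ_b / (2A) with
internal-reflection parameter A = 2.82 by default (configurable in the
geometry file).  Far boundaries are absorbing and padded.  Each collimated
source fiber is an isotropic point source buried one transport mean free
path, 1/μs′, below its surface position, deposited trilinearly on the grid.
A detector reading is the exitance-proportional boundary fluence at the
detector position; the detector plane is interpolated in log space because
the field decays near-exponentially with lateral distance (linear
interpolation biased off-grid detectors high by up to 15% at 2 mm spacing).
The arbitrary overall intensity scale cancels in calibration.

Linear systems are solved by sparse LU (symmetric-mode MMD ordering) below
8000 voxels and Jacobi-preconditioned conjugate gradients (rtol 1e-10) above;
the matrix is factorized once per scene and reused across the 8 sources.
In a homogeneous half-space the solver agrees with the extrapolated-boundary
image-source Green's function within 5% over 5–15 mm source–detector
separations at 1 mm spacing.  Refinement from 1.0 to 0.5 mm spacing moves
detector readings by at most ~3% (≥5 mm separations); the residual
h-dependence is the first-order Robin discretization, and cancels in the
self-consistent inversions below.

## Scene parameterization

A scene is an ordered region model: background (untreated prostate or
phantom matrix), optional rectal-wall layer (default thickness 2.5 mm when
enabled), optional surrounding-tissue slab, and the coagulation zone — an
ellipsoid with circular transverse cross-section (semi-axis `a` shared by
the x and z axes, longitudinal semi-axis `b`), centered at the known
treatment-fiber position.  Region labels follow a voxel-center membership
rule (`rasterize_scene`).  For the forward model, however, the zone boundary
is applied as a partial-volume occupancy: a linear ramp of one-voxel spatial
width in an approximate signed distance to the ellipsoid surface
(sphere-exact; conservative for elongated zones).  This makes the predicted
intensities differentiable in (a, b) on a fixed grid — with a crisp mask
they are a staircase, which defeats finite-difference Jacobians and the
optimizer at practical spacings.  The same occupancy is used when
synthesizing data and when inverting, so recovery tests are exact
closure tests, not grid-convergence tests.

## Inverse solver

For a calibrated frame m and model prediction p(θ), the fit minimizes

    Σ_valid w_i (log m_i − log p_i)² + τ ‖θ − θ₀‖²

over the scaled parameter vector θ (lengths in mm/10, optical properties in
natural log), with τ = 1e-4 Tikhonov pull toward the initial estimate θ₀.
Log residuals make the multiplicative instrument noise and the calibration
structure approximately homoscedastic.  Default fitted set:
{a, b, zone μa, zone μs′}; background properties can be added, or the
properties clamped for shape-only fits.

Minimization is Levenberg–Marquardt with box-bound projection: damping
λ₀ = 1e-2, ×10 on rejected steps, ÷3 on accepted ones; per-iteration scaled
step capped at 0.5; central finite-difference Jacobian (shape step 0.1 mm,
property step 1e-3 relative — forward differences bias the fixed point by
about half the step and were rejected).  Bounds: a ∈ [1, 15] mm but never
exceeding the fiber depth z₀ (the zone cannot penetrate the probe), full
length 2b bounded by the 20 mm optical window, properties within ×/÷10 of
their initial values.  A parameter finishing within 1e-6 (scaled) of a bound
sets its bound-hit flag; that is how longitudinal saturation at the window
length is reported.  Convergence: relative cost change < 1e-6, absolute cost
< 1e-14 (noiseless data decays geometrically toward zero and never satisfies
a relative test), or scaled step < 1e-4; 50 iterations maximum per stage.

The default fit is two-stage: a shape-only pre-fit with properties clamped
at their initial estimates, then the joint fit warm-started from it.
Single-stage LM from some initial radii overshot the property parameters
toward their bounds and crept along a curved valley; with staging, fits of
the same frame from initial radii 2–12 mm agree to micrometers.  Warm-started
fits (monitoring, bootstrap replicates) skip the pre-fit.

Uncertainties come from the Gauss–Newton Hessian,
cov = s² (JᵀJ + τI)⁻¹ with s² = RSS/dof, mapped to physical units; a
Jacobian column with vanishing norm (e.g. zone properties when the zone
occupies no voxels, or shape with zero contrast) marks the fit
non-identifiable and reports infinite errors for the affected parameters.
Independently, `bootstrap` refits with-replacement resamples of the 64
source–detector pairs (resampling weights enter the residuals; subsets
without replacement are available), warm-started from the full-data fit.

## Monitoring pipeline

Scans are fitted in time order, each warm-started from the previous result
(cold start available).  A non-converged scan keeps the previous estimate
and is flagged.  The radius series is smoothed by a centered 5-point moving
average (shrinking symmetric windows at the edges), from which the
boundary-to-probe distance (fiber depth − smoothed radius) and least-squares
growth rates per interval are derived.  An optional monotonic-expansion
constraint (a_t ≥ a_{t−1} − 0.3 mm) is off by default: raw reconstructions
are allowed to fluctuate and smoothing recovers the trend.  4-source mode
simply masks the inactive sources' rows; the fit proceeds on 32 channels.

## Synthetic experiments

The generator reproduces the structure of the three validation settings.

* **Phantom analog** — agar background (μa = 0.006, μs′ = 1.07 mm⁻¹ at
  750 nm; 670 and 808 nm values included), a 10 mm-radius inclusion with its
  edge 2.7 mm from the probe plane (center depth 12.7 mm), 90 mm long
  (truncated to the domain), with properties drawn from the six target
  inclusion ranges or given explicitly.  Because the inclusion is much
  longer than the 20 mm window, its fitted length saturates at the bound and
  the recovered radius carries a small model-mismatch bias — as in the
  physical experiment.
* **Treatment simulation** — an ellipsoidal zone (longitudinal/transverse
  aspect 1.25) grows from 2 mm at a constant 0.5 mm per 28 s scan at the 3 W
  reference power, scaling proportionally with power (a √t conduction law is
  available); the dual-power protocol steps 3 W → 5 W at the midpoint.
  Because the zone grows during a scan, each source's sub-frame is computed
  from the zone as it stood at that source's acquisition time; the
  reconstructor ignores this, as the real system does.  Channels carry
  multiplicative Gaussian noise (σ = 1% default).  Slow cyclical
  physiological fluctuations are modeled as a sinusoidal modulation of the
  background absorption (default amplitude 10% of μa, period 60 s) — a
  declared surrogate with invented parameters, disabled for phantom/ex vivo
  conditions.  The simulation stops with a truncation flag if the boundary
  would come within 0.5 mm of the probe.  Ground truth is recorded
  separately and never read by the reconstruction pipeline.
* **Thermometry analog** — radially symmetric Gaussian temperature maps on a
  1 mm transverse grid whose 55 °C isotherm sits at a requested radius; the
  extraction applies 3×3 Gaussian smoothing and marching squares, returning
  the maximum radial extent toward the probe side.

What these tests show: the inverse problem is well-posed under the stated
contrast (~2× scattering increase on coagulation), robust to initialization
and to realistic property errors, and the pipeline tracks growth and
plateaus correctly.  What they do not show: accuracy under real tissue
heterogeneity, probe-coupling drift, blood accumulation at the fiber tip, or
non-ellipsoidal zone shapes — the generator shares the forward model and the
binary native/coagulated idealization with the reconstructor.

## Problem sizes

Unit and acceptance tests run the reconstructions on a 42×48×30 mm domain at
3 mm spacing (2240 voxels) — chosen as the coarsest grid on which closure
recovery is still exact to ≲0.1 mm — and the forward-accuracy checks at
1–0.5 mm.  `scripts/acceptance.py` uses the same 3 mm reconstruction grid;
finer grids (1–2 mm, default domain 60×60×40 mm) improve forward fidelity
and are the intended operating point for real data, at several minutes per
fit on one core.

## Known limitations

* The planar half-space approximation ignores probe curvature; boundary
  distances are along the depth axis.
* The fitted longitudinal bound follows the full-length ≤ window convention;
  a longitudinal radius larger than half the window cannot be reported.
* Calibration assumes stable per-channel gains over a session; drift
  re-calibration is out of scope.
* The default source/detector checkerboard is a stand-in for the real fiber
  layout, which should be supplied via the geometry file.
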
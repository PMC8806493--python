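# sbdot — shape-based transrectal diffuse optical tomography

`sbdot` monitors interstitial photothermal therapy (PTT) of focal prostate
lesions with a continuous-wave transrectal optical probe.  During PTT a
near-infrared laser coagulates tissue above ~55 °C; the coagulation zone
must grow enough to ablate the target but stop before it reaches the rectal
wall.  Thermal coagulation roughly doubles the tissue's reduced scattering
coefficient μs′ and alters its absorption μa, so the expanding zone leaves a
clear signature in diffuse reflectance measured from the rectum.

Instead of reconstructing voxelwise property maps — ill-posed from 64
reflectance channels — the package fits a low-dimensional parametric model:
the coagulation zone is an ellipsoid with transverse semi-axis *a* (shared
by the lateral and depth axes) and longitudinal semi-axis *b*, centered on
the treatment fiber, embedded in a layered background.  For each scan the
solver minimizes

    Σ (log m_i − log p_i(θ))²  +  τ‖θ − θ₀‖²,   θ = (a, b, μa_zone, μs′_zone)

over the 64 source–detector pairs, where p(θ) is a finite-volume solution
of the CW photon-diffusion equation  −∇·(D∇Φ) + μa Φ = q  with a
partial-current boundary at the probe surface.  Minimization is staged
Levenberg–Marquardt with box bounds; uncertainties come from the
Gauss–Newton Hessian and from a bootstrap over measurement channels.  The
safety-critical output is the boundary-to-probe distance z₀ − a and its
growth rate.

The package includes the whole measurement pipeline: per-pair calibration
against a reference of known optical properties, a warm-started
time-series monitoring mode with 5-point smoothing, a synthetic-data
generator that emulates the phantom / ex vivo / in vivo validation
experiments (expanding zone, ≤1% multiplicative channel noise, cyclical
physiological fluctuations, dual-power 3 W → 5 W protocols), and an
MR-thermometry analog (55 °C isotherm extraction) for ground-truth
comparison.  See `docs/methods.md` for the model details and design
decisions.

## Worked example

Simulate a monitored treatment and reconstruct it, from Python:

```python
import numpy as np
from sbdot import (OpticalProperties, ProbeLayout, Grid, SceneModel,
                   EllipsoidZone, ReconstructionConfig, run_monitoring)
from sbdot.synth import GrowthProtocol, NoiseModel, simulate_treatment

native = OpticalProperties(mua=0.034, musp=0.66)     # canine prostate, 750 nm
coag   = OpticalProperties(mua=0.020, musp=1.1)      # after photocoagulation
layout = ProbeLayout()                               # 8 sources + 8 detectors
grid   = Grid((42, 48, 30), spacing=3.0)

proto = GrowthProtocol(schedule=((0.0, 112.0, 3.0), (112.0, 224.0, 5.0)),
                       initial_radius=3.0, fiber_depth=12.0)
frames, truth = simulate_treatment(
    proto, native, coag, NoiseModel(sigma=0.01, fluct_amplitude=0.0, seed=1),
    layout, grid=grid, n_post_scans=3)

template = SceneModel(background=native,
                      zone=EllipsoidZone((0, 0, 12.0), a=3.0, b=4.0),
                      zone_props=coag, grid=grid)
series = run_monitoring(frames, template, layout,
                        ReconstructionConfig(initial={"a": 3.0}))
print(series.summary())
```

Output:

```
PTT monitoring series
==============================================
scans: 11   mode: 8-source   converged: 11/11
final radius (smoothed): 9.20 mm
final boundary-to-probe distance: 2.80 mm
```

The ground-truth radius grows from 3 mm by 0.5 mm per 28 s scan at 3 W and
0.83 mm per scan after the power step, ending at 8.3 mm.  The reconstructed
series tracks the two growth rates, overshoots by under 1 mm (small, deep
zones are weakly constrained in reflectance geometry early in treatment),
and plateaus at 9.1–9.2 mm across the three post-treatment scans once the
laser stops; the reported distance is the clearance between the coagulation
boundary and the probe surface.  A single-frame fit returns a
`ShapeFitResults` with `params`, `bse`, `cov_params()`, `summary()`, and
`bootstrap()`.

The same pipeline is scriptable from the shell:

```bash
sbdot simulate --protocol dual-power --seed 7 --out run/
sbdot monitor --frames run/frames.csv --geometry run/geometry.json \
      --fiber-depth 10 --init-radius 3 --out run/
```

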
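"""Synthetic scenes, treatments and thermometry analogs.

Generates measurement data with the statistical and physical structure of
the three validation settings:

* a tissue-simulating agar phantom with a cylindrical inclusion of altered
  ("coagulated") optical properties 2.7 mm from the probe plane,
* photothermal treatments with an expanding ellipsoidal coagulation zone,
  <= 1% multiplicative instrument noise, optional slow cyclical
  physiological fluctuations of the background absorption, and a dual-power
  (3 W -> 5 W) protocol, and
* MR-thermometry-analog temperature maps on a 1 mm transverse grid whose
  55 deg C contour is the reference coagulation boundary.

The ground truth emitted next to the frames is never consumed by the
reconstruction pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .forward import DiffusionForward
from .frames import MeasurementFrame
from .geometry import EllipsoidZone, Grid, OpticalProperties, ProbeLayout, SceneModel

__all__ = [
    "GrowthProtocol",
    "NoiseModel",
    "TemperatureMap",
    "PHANTOM_BACKGROUND",
    "PHANTOM_INCLUSIONS",
    "make_phantom_scene",
    "simulate_treatment",
    "make_temperature_map",
    "extract_isotherm_radius",
    "coagulated_from_native",
]

# Agar matrix optical properties by wavelength (mm^-1), measured by the
# reference diffuse-reflectance probe.
PHANTOM_BACKGROUND: Dict[float, OpticalProperties] = {
    670.0: OpticalProperties(0.009, 1.08),
    750.0: OpticalProperties(0.006, 1.07),
    808.0: OpticalProperties(0.004, 1.01),
}

# Midpoints of the six inclusion target ranges (mua, musp) in mm^-1.
PHANTOM_INCLUSIONS: Dict[int, OpticalProperties] = {
    1: OpticalProperties(0.0085, 1.175),
    2: OpticalProperties(0.0085, 2.125),
    3: OpticalProperties(0.0330, 2.125),
    4: OpticalProperties(0.0550, 2.125),
    5: OpticalProperties(0.0330, 3.125),
    6: OpticalProperties(0.0550, 3.125),
}

PHANTOM_INCLUSION_RADIUS = 10.0   # mm (20 mm diameter well)
PHANTOM_EDGE_GAP = 2.7            # mm edge-to-edge inclusion-to-probe separation
PHANTOM_INCLUSION_LENGTH = 90.0   # mm fill height of the well


def make_phantom_scene(inclusion: Optional[int] = None,
                       zone_props: Optional[OpticalProperties] = None,
                       wavelength_nm: float = 750.0,
                       radius: float = PHANTOM_INCLUSION_RADIUS,
                       edge_gap: float = PHANTOM_EDGE_GAP,
                       length: float = PHANTOM_INCLUSION_LENGTH,
                       grid: Optional[Grid] = None) -> SceneModel:
    """Phantom-analog scene: agar background plus a long coagulation-like inclusion.

    The cylindrical well is represented as an ellipsoid of transverse
    semi-axis ``radius`` and longitudinal semi-axis ``length/2``, truncated
    by the domain.  Zone center depth = edge_gap + radius.
    """
    if (inclusion is None) == (zone_props is None):
        raise ValueError("give exactly one of inclusion id or explicit zone_props")
    if inclusion is not None:
        if inclusion not in PHANTOM_INCLUSIONS:
            raise ValueError(f"unknown inclusion id {inclusion}; expected 1..6")
        zone_props = PHANTOM_INCLUSIONS[inclusion]
    if wavelength_nm not in PHANTOM_BACKGROUND:
        raise ValueError(f"no phantom background at {wavelength_nm} nm")
    grid = grid or Grid()
    b = length / 2.0
    b = min(b, grid.domain[1] / 2.0)  # truncate the well to the domain
    zone = EllipsoidZone(center=(0.0, 0.0, edge_gap + radius), a=radius, b=b)
    return SceneModel(
        background=PHANTOM_BACKGROUND[wavelength_nm],
        zone=zone,
        zone_props=zone_props,
        grid=grid,
    )


def coagulated_from_native(native: OpticalProperties,
                           mua_factor: float = 0.6,
                           musp_factor: float = 2.0) -> OpticalProperties:
    """Default coagulation contrast: scattering doubles, absorption drops ~40%."""
    return native.scaled(mua_factor, musp_factor)


@dataclass(frozen=True)
class GrowthProtocol:
    """Laser power schedule and coagulation growth law.

    ``schedule`` is a list of contiguous (start_s, end_s, watts) intervals.
    The default law advances the radius by a constant increment per scan
    while lasing, ~0.5 mm per 28 s scan at the 3 W reference power, scaled
    proportionally with power; a sqrt-time conduction law is available.
    """

    schedule: Tuple[Tuple[float, float, float], ...] = ((0.0, 744.0, 3.0),)
    rate_mm_per_scan: float = 0.5
    ref_power_w: float = 3.0
    rate_scales_with_power: bool = True
    law: str = "linear"            # "linear" or "sqrt"
    initial_radius: float = 2.0    # mm at treatment start
    fiber_depth: float = 10.0      # mm, treatment fiber below the probe plane
    aspect_ratio: float = 1.25     # longitudinal/transverse semi-axis ratio
    scan_period: float = 28.0      # s (28 for 8-source, 14 for 4-source scans)

    def __post_init__(self) -> None:
        sched = tuple((float(a), float(b), float(p)) for a, b, p in self.schedule)
        object.__setattr__(self, "schedule", sched)
        for (a, b, p) in sched:
            if b <= a or p < 0:
                raise ValueError("schedule intervals must have end > start and power >= 0")
        for (a0, b0, _), (a1, _, _) in zip(sched, sched[1:]):
            if not math.isclose(b0, a1):
                raise ValueError("schedule intervals must be contiguous and non-overlapping")
        if self.rate_mm_per_scan < 0:
            raise ValueError("growth rate must be >= 0")
        if self.law not in ("linear", "sqrt"):
            raise ValueError("law must be 'linear' or 'sqrt'")

    @property
    def end_time(self) -> float:
        return self.schedule[-1][1]

    def power_at(self, t: float) -> float:
        for (a, b, p) in self.schedule:
            if a <= t < b:
                return p
        return 0.0

    def _rate_mm_per_s(self, power: float) -> float:
        r = self.rate_mm_per_scan / self.scan_period
        if self.rate_scales_with_power:
            r *= power / self.ref_power_w
        return r

    def radius_at(self, t: float) -> float:
        """Ground-truth transverse radius at time t (laser-off => frozen)."""
        r = self.initial_radius
        lased = 0.0
        for (a, b, p) in self.schedule:
            if t <= a or p == 0:
                continue
            dt = min(t, b) - a
            if dt <= 0:
                continue
            if self.law == "linear":
                r += self._rate_mm_per_s(p) * dt
            else:  # sqrt-of-lasing-time conduction law
                k = self._rate_mm_per_s(p)
                r += k * (math.sqrt(lased + dt) - math.sqrt(lased)) * 2.0 * math.sqrt(max(self.end_time, 1.0))
            lased += dt
        return r


@dataclass(frozen=True)
class NoiseModel:
    """Instrument and physiological noise applied to predicted intensities.

    ``sigma`` is the per-channel multiplicative Gaussian fraction (<1%
    instrument noise by default).  The physiological term is a slow sinusoid
    modulating the background absorption — a declared surrogate for the
    cyclical in vivo fluctuations, with invented default amplitude 10% of
    background mua and period 60 s; set amplitude 0 for phantom/ex vivo
    conditions.
    """

    sigma: float = 0.01
    fluct_amplitude: float = 0.1
    fluct_period_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.fluct_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def instrument_only(cls, sigma: float = 0.01, seed: int = 0) -> "NoiseModel":
        return cls(sigma=sigma, fluct_amplitude=0.0, seed=seed)

    def mua_modulation(self, t: float) -> float:
        if self.fluct_amplitude == 0:
            return 1.0
        return 1.0 + self.fluct_amplitude * math.sin(2 * math.pi * t / self.fluct_period_s)


def simulate_treatment(protocol: GrowthProtocol,
                       native: OpticalProperties,
                       coagulated: Optional[OpticalProperties],
                       noise: NoiseModel,
                       layout: ProbeLayout,
                       grid: Optional[Grid] = None,
                       n_post_scans: int = 4,
                       per_source_growth: bool = True,
                       wavelength_nm: float = 750.0,
                       active_sources: Optional[Sequence[int]] = None,
                       ) -> Tuple[List[MeasurementFrame], pd.DataFrame]:
    """Simulate a monitored PTT treatment.

    Returns (frames, truth) where truth records the ground-truth radius at
    each scan midpoint.  Because the zone grows during the scan period, each
    source's sub-frame is computed from the zone as it stood at that
    source's acquisition time within the scan; the reconstructor ignores
    this, as the real system does.  The simulation stops with a truncation
    flag if the boundary would come within 0.5 mm of the probe surface.
    """
    if coagulated is None:
        coagulated = coagulated_from_native(native)
    grid = grid or Grid()
    rng = np.random.default_rng(noise.seed)
    period = protocol.scan_period
    n_scans = int(round(protocol.end_time / period)) + n_post_scans
    n_src = len(layout.sources)
    active = list(range(n_src)) if active_sources is None else list(active_sources)

    frames: List[MeasurementFrame] = []
    truth_rows = []
    truncated = False
    for k in range(n_scans):
        t_start = k * period
        t_mid = t_start + period / 2.0
        r_mid = protocol.radius_at(t_mid)
        if protocol.fiber_depth - protocol.radius_at(t_start + period) < 0.5:
            truncated = True
            break
        intensities = np.ones((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        source_times = [t_start + (s + 0.5) * period / n_src for s in range(n_src)]
        cache: Dict[Tuple[float, float], np.ndarray] = {}
        for s in active:
            ts = source_times[s] if per_source_growth else t_mid
            r = protocol.radius_at(ts)
            mua_bg = native.mua * noise.mua_modulation(ts)
            key = (round(r, 6), round(mua_bg, 9))
            if key not in cache:
                scene = SceneModel(
                    background=OpticalProperties(mua_bg, native.musp),
                    zone=EllipsoidZone((0.0, 0.0, protocol.fiber_depth),
                                       a=r, b=protocol.aspect_ratio * r),
                    zone_props=coagulated,
                    grid=grid,
                )
                cache[key] = DiffusionForward(scene, layout).predict()
            intensities[s, :] = cache[key][s, :]
            mask[s, :] = True
        if noise.sigma > 0:
            gains = 1.0 + noise.sigma * rng.standard_normal((8, 8))
            intensities = intensities * np.clip(gains, 0.05, None)
        frames.append(MeasurementFrame(
            time_s=t_mid, wavelength_nm=wavelength_nm,
            intensities=intensities, mask=mask, calibrated=True,
            meta={"seed": noise.seed, "scan_index": k,
                  "power_W": protocol.power_at(t_mid)},
        ))
        truth_rows.append({
            "time_s": t_mid,
            "true_radius_mm": r_mid,
            "power_W": protocol.power_at(t_mid),
            "lasing": protocol.power_at(t_mid) > 0,
        })
    truth = pd.DataFrame(truth_rows)
    truth.attrs["truncated"] = truncated
    return frames, truth


@dataclass(frozen=True)
class TemperatureMap:
    """2D transverse temperature grid (deg C) around the treatment fiber."""

    values: np.ndarray          # (n, n), deg C
    pixel_mm: float = 1.0
    center_px: Tuple[float, float] = (0.0, 0.0)
    sub_threshold: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("temperature map must be finite")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be > 0")
        object.__setattr__(self, "values", vals)


def make_temperature_map(true_radius: Optional[float], peak: float = 90.0,
                         baseline: float = 37.0, sigma_mm: Optional[float] = None,
                         extent_mm: float = 40.0, pixel_mm: float = 1.0,
                         threshold: float = 55.0) -> TemperatureMap:
    """Radially symmetric Gaussian temperature profile on a 1 mm grid.

    If ``sigma_mm`` is not given it is solved so that the ``threshold``
    isotherm sits exactly at ``true_radius``:
    T(r) = baseline + (peak - baseline) exp(-r^2 / (2 sigma^2)).
    """
    n = int(round(extent_mm / pixel_mm))
    ax = (np.arange(n) + 0.5) * pixel_mm - extent_mm / 2
    X, Z = np.meshgrid(ax, ax, indexing="ij")
    R2 = X**2 + Z**2
    center_px = ((extent_mm / 2) / pixel_mm - 0.5, (extent_mm / 2) / pixel_mm - 0.5)
    if true_radius is None:
        return TemperatureMap(np.full((n, n), baseline), pixel_mm, center_px,
                              sub_threshold=baseline <= threshold)
    sub = peak <= threshold
    if sigma_mm is None:
        if sub:
            sigma_mm = true_radius  # shape only; the map stays sub-threshold
        else:
            sigma_mm = true_radius / math.sqrt(
                2.0 * math.log((peak - baseline) / (threshold - baseline)))
    vals = baseline + (peak - baseline) * np.exp(-R2 / (2.0 * sigma_mm**2))
    return TemperatureMap(vals, pixel_mm, center_px, sub_threshold=sub)


def extract_isotherm_radius(tmap: TemperatureMap, threshold: float = 55.0):
    """Isotherm radius from a temperature map (3x3 Gaussian smoothing first).

    Returns (radius_mm, contour_xy_mm, flags).  The radius is the maximum
    radial distance from the map center toward the probe side (negative
    second axis), the safety-relevant direction; the contour is extracted by
    marching squares.  With no super-threshold pixels the radius is None and
    ``sub_threshold`` is flagged; a map entirely above threshold yields a
    degenerate frame contour, flagged ``degenerate``.
    """
    smoothed = gaussian_filter(tmap.values, sigma=0.5, mode="nearest")
    flags = {"sub_threshold": False, "degenerate": False}
    if not np.any(smoothed > threshold):
        flags["sub_threshold"] = True
        return None, None, flags
    contours = measure.find_contours(smoothed, threshold)
    if not contours:
        # everything above threshold: the boundary is the image frame
        flags["degenerate"] = True
        n = smoothed.shape[0]
        frame = np.array([[0, 0], [0, n - 1], [n - 1, n - 1], [n - 1, 0], [0, 0]], float)
        contours = [frame]
        if np.all(smoothed > threshold):
            pass
    contour = max(contours, key=len)
    cx, cz = tmap.center_px
    xy_mm = (contour - np.array([cx, cz])) * tmap.pixel_mm
    toward_probe = xy_mm[xy_mm[:, 1] <= 0.0]
    pts = toward_probe if len(toward_probe) else xy_mm
    radius = float(np.max(np.hypot(pts[:, 0], pts[:, 1])))
    if np.all(smoothed.ravel() > threshold):
        flags["degenerate"] = True
    return radius, xy_mm, flags
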
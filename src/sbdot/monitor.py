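"""Treatment monitoring: sequential reconstruction over a scan time series.

Each scan is fitted warm-started from the previous scan's result (cold start
available), the transverse-radius series is smoothed with a centered
moving average, and the safety-relevant quantities — boundary-to-probe
distance and growth rate — are derived from the smoothed series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .frames import MeasurementFrame
from .geometry import ProbeLayout, SceneModel
from .reconstruct import ReconstructionConfig, ShapeFit, ShapeFitResults

__all__ = ["MonitoringSeries", "run_monitoring", "smooth_series", "growth_rate"]


def smooth_series(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average; edges use shrinking symmetric windows.

    Length-preserving: sample i averages over [i-k, i+k] with
    k = min(window//2, i, n-1-i).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = np.empty_like(vals)
    n = vals.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = vals[i - k : i + k + 1].mean()
    return out


def growth_rate(series: Sequence[float], times: Sequence[float],
                interval: Optional[Tuple[float, float]] = None,
                scan_period: float = 28.0) -> Dict[str, float]:
    """Least-squares slope of the (smoothed) radius over a time interval.

    Returns the rate in mm/s and mm per scan (``scan_period`` seconds).
    """
    r = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if interval is not None:
        m = (t >= interval[0]) & (t <= interval[1])
        r, t = r[m], t[m]
    if r.size < 2:
        raise ValueError("growth rate needs at least 2 samples in the interval")
    slope = float(np.polyfit(t, r, 1)[0])
    return {"mm_per_s": slope, "mm_per_scan": slope * scan_period}


@dataclass
class MonitoringSeries:
    """Per-scan reconstructions and derived series for one treatment."""

    results: List[ShapeFitResults]
    table: pd.DataFrame
    scan_mode: int = 8  # number of active sources

    def summary(self) -> str:
        t = self.table
        lines = [
            "PTT monitoring series",
            "=" * 46,
            f"scans: {len(t)}   mode: {self.scan_mode}-source"
            f"   converged: {int(t.converged.sum())}/{len(t)}",
            f"final radius (smoothed): {t.radius_smoothed_mm.iloc[-1]:.2f} mm",
            f"final boundary-to-probe distance: {t.distance_to_probe_mm.iloc[-1]:.2f} mm",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, ax=None, truth: Optional[pd.DataFrame] = None):
        """Radius-vs-time plot: raw fits, smoothed trend, optional truth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        t = self.table
        ax.plot(t.time_s, t.radius_mm, "k.-", lw=0.8, alpha=0.6, label="per-scan fit")
        ax.plot(t.time_s, t.radius_smoothed_mm, "r-", lw=2, label="5-point smoothed")
        if truth is not None:
            ax.plot(truth.time_s, truth.true_radius_mm, "b--", lw=1,
                    label="ground truth")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("transverse radius (mm)")
        ax.legend(frameon=False)
        return ax


def run_monitoring(frames: Sequence[MeasurementFrame], scene_template: SceneModel,
                   layout: ProbeLayout, config: Optional[ReconstructionConfig] = None,
                   warm_start: bool = True, monotonic: bool = False,
                   monotonic_tol: float = 0.3,
                   powers: Optional[Sequence[float]] = None,
                   smooth_window: int = 5) -> MonitoringSeries:
    """Reconstruct every scan of a time-ordered series.

    A non-converged frame keeps the previous estimate (flagged, not fatal).
    With ``monotonic`` the fitted radius is constrained to
    a_t >= a_{t-1} - monotonic_tol, reflecting the monotonically expanding
    coagulation boundary; off by default since smoothing alone recovers the
    trend from fluctuating reconstructions.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to monitor")
    times = [f.time_s for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    config = config or ReconstructionConfig()

    results: List[ShapeFitResults] = []
    prev: Optional[ShapeFitResults] = None
    rows = []
    n_sources_active = None
    for frame in frames:
        cfg = ReconstructionConfig(**{**config.__dict__})
        cfg.initial = dict(config.initial)
        cfg.bounds = dict(config.bounds)
        if monotonic and prev is not None:
            lo = max(cfg.a_bounds[0], prev.params["a"] - monotonic_tol)
            cfg.bounds.setdefault("a", (lo, cfg.a_bounds[1]))
        model = ShapeFit(frame, scene_template, layout, cfg)
        start = dict(prev.params) if (warm_start and prev is not None) else None
        res = model.fit(start=start)
        if not res.converged and prev is not None:
            warnings.warn(f"scan at t={frame.time_s:.0f}s did not converge; holding previous estimate")
            held = dict(prev.params)
            res.params.update(held)
        results.append(res)
        prev = res
        n_sources_active = int(np.any(frame.mask, axis=1).sum())
        rows.append({
            "time_s": frame.time_s,
            "radius_mm": res.params["a"],
            "converged": res.converged,
        })
    table = pd.DataFrame(rows)
    table["radius_smoothed_mm"] = smooth_series(table["radius_mm"].to_numpy(), smooth_window)
    fiber_depth = scene_template.zone.center[2]
    table["distance_to_probe_mm"] = fiber_depth - table["radius_smoothed_mm"]
    table["power_W"] = list(powers) if powers is not None else np.nan
    return MonitoringSeries(results=results, table=table,
                            scan_mode=n_sources_active or 8)
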
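"""File formats: frame CSV, geometry/calibration/results JSON, run-config YAML.

Conventions (validated on load): source/detector ids are 0-based, lengths in
mm, optical coefficients in mm^-1, times in s; frame CSVs are comma-separated
UTF-8 with a mandatory header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSet
from .frames import MeasurementFrame
from .geometry import Grid, ProbeLayout

__all__ = [
    "read_frames",
    "write_frames",
    "load_geometry",
    "save_geometry",
    "load_calibration",
    "save_calibration",
    "load_run_config",
]

FRAME_COLUMNS = ["time_s", "wavelength_nm", "source_id", "detector_id", "intensity"]


class FormatError(ValueError):
    """Raised on malformed input files."""


def read_frames(path) -> List[MeasurementFrame]:
    """Read a frames CSV into time/wavelength-grouped MeasurementFrames.

    Missing (source, detector) combinations are masked out; duplicates and
    non-numeric intensities are errors, with the offending CSV line reported.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    for col in ("time_s", "wavelength_nm", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = coerced
    for col in ("source_id", "detector_id"):
        ids = pd.to_numeric(df[col], errors="coerce")
        if ids.isna().any() or not np.array_equal(ids, ids.astype(int)):
            raise FormatError(f"{path}: {col} must be integers 0-7")
        if ids.min() < 0 or ids.max() > 7:
            raise FormatError(f"{path}: {col} out of range 0-7")
        df[col] = ids.astype(int)

    dup = df.duplicated(subset=["time_s", "wavelength_nm", "source_id", "detector_id"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise FormatError(f"{path}: duplicate (time, wavelength, source, detector) at line {line}")

    has_mask = "mask" in df.columns
    frames = []
    for (t, wl), group in df.groupby(["time_s", "wavelength_nm"], sort=True):
        intensities = np.ones((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        s = group["source_id"].to_numpy()
        d = group["detector_id"].to_numpy()
        intensities[s, d] = group["intensity"].to_numpy()
        mask[s, d] = True
        if has_mask:
            mask[s, d] &= group["mask"].to_numpy().astype(bool)
        mask &= np.isfinite(intensities) & (intensities > 0)
        frames.append(MeasurementFrame(time_s=float(t), wavelength_nm=float(wl),
                                       intensities=intensities, mask=mask))
    return frames


def write_frames(path, frames: List[MeasurementFrame], include_masked: bool = False) -> None:
    rows = []
    for f in frames:
        for s in range(8):
            for d in range(8):
                if f.mask[s, d] or include_masked:
                    rows.append({
                        "time_s": f.time_s, "wavelength_nm": f.wavelength_nm,
                        "source_id": s, "detector_id": d,
                        "intensity": f.intensities[s, d],
                        "mask": bool(f.mask[s, d]),
                    })
    pd.DataFrame(rows, columns=FRAME_COLUMNS + ["mask"]).to_csv(path, index=False)


# ----- geometry JSON --------------------------------------------------------


def save_geometry(path, layout: ProbeLayout, grid: Optional[Grid] = None,
                  refractive_mismatch: float = 2.82) -> None:
    grid = grid or Grid()
    payload = {
        "units": {"length": "mm", "coefficient": "mm^-1", "time": "s", "ids": "0-based"},
        "window_length_mm": layout.window_length,
        "window_width_mm": layout.window_width,
        "sources": [list(p) for p in layout.sources],
        "detectors": [list(p) for p in layout.detectors],
        "refractive_index_mismatch": refractive_mismatch,
        "grid_spacing_mm": grid.spacing,
        "domain_mm": list(grid.domain),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry(path) -> Tuple[ProbeLayout, Grid, float]:
    """Returns (layout, grid, refractive_mismatch)."""
    data = json.loads(Path(path).read_text())
    units = data.get("units", {})
    if units and units.get("length", "mm") != "mm":
        raise FormatError(f"{path}: geometry lengths must be in mm")
    try:
        layout = ProbeLayout(
            window_length=data["window_length_mm"],
            window_width=data["window_width_mm"],
            sources=tuple(tuple(p) for p in data["sources"]),
            detectors=tuple(tuple(p) for p in data["detectors"]),
        )
        grid = Grid(domain=tuple(data["domain_mm"]), spacing=data["grid_spacing_mm"])
        A = float(data.get("refractive_index_mismatch", 2.82))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid geometry file: {exc}") from exc
    return layout, grid, A


# ----- calibration JSON -----------------------------------------------------


def save_calibration(path, cal: CalibrationSet) -> None:
    payload = {
        "provenance": cal.provenance,
        "wavelengths": {
            str(wl): {
                "factors": cal.factors[wl].tolist(),
                "valid": cal.valid[wl].astype(int).tolist(),
            }
            for wl in cal.wavelengths()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path) -> CalibrationSet:
    data = json.loads(Path(path).read_text())
    cal = CalibrationSet(provenance=data.get("provenance", ""))
    try:
        for wl, block in data["wavelengths"].items():
            cal.add(float(wl), np.array(block["factors"], dtype=float),
                    np.array(block["valid"], dtype=bool))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid calibration file: {exc}") from exc
    return cal


# ----- run config YAML ------------------------------------------------------


def load_run_config(path) -> Dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: run config must be a YAML mapping")
    return data
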
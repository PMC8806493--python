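"""Per-pair calibration factors from a reference of known optical properties.

Calibration relates measured to model-predicted intensities channel by
channel: factor(s, d) = measured(s, d) / predicted(s, d).  The reference can
be a homogeneous phantom of known properties, or — in tissue — the averaged
pre-treatment baseline frames with native properties taken from a
diffuse-reflectance probe or literature values.  Because the factor is a
ratio, it is invariant to a global source-power rescaling applied to both the
measurement and the model, and it absorbs the solver's arbitrary intensity
units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable

import numpy as np

from .forward import DiffusionForward
from .frames import MeasurementFrame, average_frames
from .geometry import ProbeLayout, SceneModel

__all__ = ["CalibrationSet", "compute_factors", "apply_calibration", "calibrate_from_baseline"]


@dataclass
class CalibrationSet:
    """Per-wavelength 8x8 calibration factors with validity masks."""

    factors: Dict[float, np.ndarray] = field(default_factory=dict)
    valid: Dict[float, np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def add(self, wavelength_nm: float, factors: np.ndarray, valid: np.ndarray) -> None:
        factors = np.asarray(factors, dtype=float)
        valid = np.asarray(valid, dtype=bool)
        if factors.shape != (8, 8) or valid.shape != (8, 8):
            raise ValueError("calibration factors and mask must be 8x8")
        if np.any(valid & ~(np.isfinite(factors) & (factors > 0))):
            raise ValueError("valid calibration factors must be positive and finite")
        self.factors[float(wavelength_nm)] = factors
        self.valid[float(wavelength_nm)] = valid

    def wavelengths(self):
        return sorted(self.factors)


def compute_factors(reference_frame: MeasurementFrame, reference_scene: SceneModel,
                    layout: ProbeLayout, provenance: str = "reference measurement",
                    ) -> CalibrationSet:
    """Calibration factors from a reference frame and its known scene.

    Channels with nonpositive measured or predicted intensity are masked with
    a warning rather than failing the whole calibration.
    """
    predicted = DiffusionForward(reference_scene, layout).predict()
    measured = reference_frame.intensities
    valid = reference_frame.mask & (measured > 0) & (predicted > 0)
    n_dropped = int(reference_frame.mask.sum() - valid.sum())
    if n_dropped:
        warnings.warn(f"calibration masked {n_dropped} channel(s) with nonpositive values")
    factors = np.ones((8, 8))
    np.divide(measured, predicted, out=factors, where=valid)
    cal = CalibrationSet(provenance=provenance)
    cal.add(reference_frame.wavelength_nm, factors, valid)
    return cal


def calibrate_from_baseline(baseline_frames: Iterable[MeasurementFrame],
                            native_scene: SceneModel, layout: ProbeLayout) -> CalibrationSet:
    """Native-tissue calibration from the averaged pre-treatment frames."""
    mean_frame = average_frames(baseline_frames)
    return compute_factors(mean_frame, native_scene, layout,
                           provenance=f"native-tissue baseline (n={mean_frame.meta['averaged_n']})")


def apply_calibration(frame: MeasurementFrame, cal: CalibrationSet) -> MeasurementFrame:
    """Calibrated frame: intensity / factor, masks combined."""
    if frame.calibrated:
        raise ValueError("frame is already calibrated")
    wl = float(frame.wavelength_nm)
    if wl not in cal.factors:
        raise ValueError(
            f"no calibration factors for wavelength {wl} nm "
            f"(available: {cal.wavelengths()})"
        )
    factors, valid = cal.factors[wl], cal.valid[wl]
    mask = frame.mask & valid
    out = np.where(valid, frame.intensities / np.where(valid, factors, 1.0), frame.intensities)
    return frame.replace(intensities=out, mask=mask, calibrated=True)
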
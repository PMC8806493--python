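"""Measurement frames: one scan's 8x8 intensity matrix with a channel mask."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

DEFAULT_WAVELENGTHS = (670.0, 750.0, 808.0)

__all__ = ["MeasurementFrame", "DEFAULT_WAVELENGTHS", "average_frames"]


@dataclass(frozen=True)
class MeasurementFrame:
    """One scan: 8x8 intensities indexed [source, detector] plus channel mask.

    ``mask`` marks valid channels; masked-out entries carry no constraint
    (e.g. 670 nm channels lost below the measurement limit at high
    absorption).  ``calibrated`` guards against double application of the
    per-pair calibration factors.
    """

    time_s: float
    wavelength_nm: float
    intensities: np.ndarray
    mask: Optional[np.ndarray] = None
    dark_corrected: bool = True
    calibrated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(self.intensities, dtype=float)
        if vals.shape != (8, 8):
            raise ValueError(f"intensities must be 8x8, got {vals.shape}")
        mask = self.mask
        mask = np.ones((8, 8), dtype=bool) if mask is None else np.array(mask, dtype=bool)
        if mask.shape != (8, 8):
            raise ValueError(f"mask must be 8x8, got {mask.shape}")
        bad = mask & ~(np.isfinite(vals) & (vals > 0))
        mask = mask & ~bad
        object.__setattr__(self, "intensities", vals)
        object.__setattr__(self, "mask", mask)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.intensities[self.mask]

    def replace(self, **kw) -> "MeasurementFrame":
        return replace(self, **kw)


def average_frames(frames: Iterable[MeasurementFrame]) -> MeasurementFrame:
    """Channel-wise mean of repeated frames (e.g. a pre-treatment baseline).

    A channel is valid in the average only if valid in every input frame.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("cannot average an empty list of frames")
    wl = frames[0].wavelength_nm
    if any(f.wavelength_nm != wl for f in frames):
        raise ValueError("cannot average frames of different wavelengths")
    if any(f.calibrated != frames[0].calibrated for f in frames):
        raise ValueError("cannot mix calibrated and raw frames")
    stack = np.stack([f.intensities for f in frames])
    mask = np.logical_and.reduce([f.mask for f in frames])
    mean = np.where(mask, stack.mean(axis=0), 1.0)  # placeholder in masked slots
    return MeasurementFrame(
        time_s=float(np.mean([f.time_s for f in frames])),
        wavelength_nm=wl,
        intensities=mean,
        mask=mask,
        dark_corrected=all(f.dark_corrected for f in frames),
        calibrated=frames[0].calibrated,
        meta={"averaged_n": len(frames)},
    )
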
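"""Parameter scaling conventions shared by the forward Jacobian and the fit.

Shape parameters (a, b) are lengths and are scaled by 1/10 (mm -> mm/10) so
that all fitted quantities are O(1); optical properties are fitted in natural
log space, which both enforces positivity and makes relative perturbations
uniform.
"""

from __future__ import annotations

import math

SHAPE_PARAMS = ("a", "b")
PROPERTY_PARAMS = ("zone_mua", "zone_musp", "bg_mua", "bg_musp")
ALL_PARAMS = SHAPE_PARAMS + PROPERTY_PARAMS

LENGTH_SCALE = 10.0  # mm per scaled unit


def is_shape(name: str) -> bool:
    if name not in ALL_PARAMS:
        raise ValueError(f"unknown parameter {name!r}")
    return name in SHAPE_PARAMS


def scale(name: str, value: float) -> float:
    """Physical value -> internal scaled value."""
    if is_shape(name):
        return value / LENGTH_SCALE
    return math.log(value)


def unscale(name: str, u: float) -> float:
    """Internal scaled value -> physical value."""
    if is_shape(name):
        return u * LENGTH_SCALE
    return math.exp(u)


def d_physical_d_scaled(name: str, u: float) -> float:
    """Derivative of the physical parameter w.r.t. its scaled version."""
    if is_shape(name):
        return LENGTH_SCALE
    return math.exp(u)


def fd_step(name: str, grid_spacing: float) -> float:
    """Forward-difference step in scaled units.

    Shape steps are 0.1 mm: the partial-volume zone boundary keeps predicted
    intensities differentiable at sub-voxel steps, and coarser grid-linked
    steps visibly bias the Jacobian.  Property steps are a 1e-3 relative
    perturbation, i.e. an absolute 1e-3 step in log space.
    """
    if is_shape(name):
        return 0.1 / LENGTH_SCALE
    return 1e-3
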
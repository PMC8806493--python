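"""Probe and scene geometry for transrectal reflectance DOT.

Coordinate frame
----------------
Origin at the centre of the probe's optical window, on the probe surface:

* ``x`` — transverse axis (window width, default 16 mm),
* ``y`` — longitudinal axis (window length, default 20 mm),
* ``z`` — depth into tissue (probe surface at ``z = 0``).

The cylindrical probe surface is approximated as a plane; the 25 mm probe
curvature is neglected, so boundary distances are measured along the depth
axis only.

The photocoagulation zone is an ellipsoid with a circular cross-section in
the transverse (x–z) plane: one transverse semi-axis ``a`` shared by x and z,
and one longitudinal semi-axis ``b`` along y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "ProbeLayout",
    "EllipsoidZone",
    "SceneModel",
    "Grid",
    "rasterize_scene",
    "distance_to_probe",
    "LABEL_BACKGROUND",
    "LABEL_WALL",
    "LABEL_SURROUND",
    "LABEL_ZONE",
]

LABEL_BACKGROUND = 0
LABEL_WALL = 1
LABEL_SURROUND = 2
LABEL_ZONE = 3


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption ``mua`` and reduced scattering ``musp`` coefficients (mm^-1)."""

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if not (self.mua > 0 and math.isfinite(self.mua)):
            raise ValueError(f"mua must be positive and finite, got {self.mua}")
        if not (self.musp > 0 and math.isfinite(self.musp)):
            raise ValueError(f"musp must be positive and finite, got {self.musp}")

    @property
    def diffusion(self) -> float:
        """Diffusion coefficient D = 1 / (3 (mua + musp)), in mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mueff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mua (mua + musp)), mm^-1."""
        return math.sqrt(3.0 * self.mua * (self.mua + self.musp))

    def scaled(self, mua_factor: float = 1.0, musp_factor: float = 1.0) -> "OpticalProperties":
        return OpticalProperties(self.mua * mua_factor, self.musp * musp_factor)


@dataclass(frozen=True)
class EllipsoidZone:
    """Ellipsoidal photocoagulation zone.

    ``center`` is (x0, y0, z0) in mm with z0 the depth of the treatment fiber
    below the probe surface.  ``a`` is the transverse semi-axis (applies to
    both x and z), ``b`` the longitudinal semi-axis (y).
    """

    center: tuple[float, float, float]
    a: float
    b: float

    def __post_init__(self) -> None:
        if len(self.center) != 3:
            raise ValueError("center must be a 3-vector (x0, y0, z0)")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if not self.a > 0:
            raise ValueError(f"transverse semi-axis a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"longitudinal semi-axis b must be > 0, got {self.b}")
        if self.center[2] - self.a < -1e-12:
            raise ValueError(
                f"zone penetrates the probe surface: z0 - a = "
                f"{self.center[2] - self.a:.3f} mm < 0"
            )

    def quadratic_form(self, x, y, z):
        """((x-x0)/a)^2 + ((z-z0)/a)^2 + ((y-y0)/b)^2 as an array."""
        x0, y0, z0 = self.center
        return ((x - x0) ** 2 + (z - z0) ** 2) / self.a**2 + (y - y0) ** 2 / self.b**2

    def contains(self, point: Sequence[float]) -> bool:
        """Boundary-inclusive membership test for a single point (mm)."""
        x, y, z = point
        return bool(self.quadratic_form(x, y, z) <= 1.0 + 1e-12)

    @property
    def distance_to_probe(self) -> float:
        """Closest approach of the zone boundary to the probe plane: z0 - a (mm)."""
        return self.center[2] - self.a


def distance_to_probe(zone: EllipsoidZone) -> float:
    """Transverse clearance between the coagulation boundary and the probe (mm)."""
    return zone.distance_to_probe


def _checkerboard_positions(window_width: float, window_length: float):
    """Default 4x4 alternating source/detector layout spanning the window."""
    xs = np.linspace(-window_width / 2, window_width / 2, 9)[1::2]   # 4 columns
    ys = np.linspace(-window_length / 2, window_length / 2, 9)[1::2]  # 4 rows
    sources, detectors = [], []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            (sources if (i + j) % 2 == 0 else detectors).append((float(x), float(y)))
    return sources, detectors


@dataclass(frozen=True)
class ProbeLayout:
    """Positions of the 8 source and 8 detector fibers within the optical window.

    Positions are (x, y) mm on the probe plane z = 0.
    """

    window_length: float = 20.0
    window_width: float = 16.0
    sources: tuple[tuple[float, float], ...] = ()
    detectors: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        sources = self.sources
        detectors = self.detectors
        if not sources and not detectors:
            sources, detectors = _checkerboard_positions(self.window_width, self.window_length)
        object.__setattr__(self, "sources", tuple((float(a), float(b)) for a, b in sources))
        object.__setattr__(self, "detectors", tuple((float(a), float(b)) for a, b in detectors))
        if len(self.sources) != 8 or len(self.detectors) != 8:
            raise ValueError(
                f"expected 8 sources and 8 detectors, got "
                f"{len(self.sources)} and {len(self.detectors)}"
            )
        hw, hl = self.window_width / 2 + 1e-9, self.window_length / 2 + 1e-9
        for name, pts in (("source", self.sources), ("detector", self.detectors)):
            for x, y in pts:
                if abs(x) > hw or abs(y) > hl:
                    raise ValueError(f"{name} at ({x}, {y}) lies outside the optical window")
        for s in self.sources:
            for d in self.detectors:
                if abs(s[0] - d[0]) < 1e-9 and abs(s[1] - d[1]) < 1e-9:
                    raise ValueError(f"source and detector coincide at {s}")

    @property
    def n_pairs(self) -> int:
        return len(self.sources) * len(self.detectors)

    def mirrored_x(self) -> "ProbeLayout":
        """Layout reflected about the x = 0 plane (sources stay sources)."""
        return ProbeLayout(
            self.window_length,
            self.window_width,
            tuple((-x, y) for x, y in self.sources),
            tuple((-x, y) for x, y in self.detectors),
        )


@dataclass(frozen=True)
class Grid:
    """Uniform voxel grid over the half-space domain.

    ``domain`` = (Lx, Ly, Lz) mm; x in [-Lx/2, Lx/2], y in [-Ly/2, Ly/2],
    z in [0, Lz].  Voxel centers at (i + 1/2) * spacing offsets.
    """

    domain: tuple[float, float, float] = (60.0, 60.0, 40.0)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", tuple(float(d) for d in self.domain))
        if not self.spacing > 0:
            raise ValueError("grid spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(max(1, round(d / self.spacing)) for d in self.domain)

    def axes(self):
        nx, ny, nz = self.shape
        h = self.spacing
        x = (np.arange(nx) + 0.5) * h - self.domain[0] / 2
        y = (np.arange(ny) + 0.5) * h - self.domain[1] / 2
        z = (np.arange(nz) + 0.5) * h
        return x, y, z

    def meshgrid(self):
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")


@dataclass(frozen=True)
class SceneModel:
    """Region model of the interrogated volume.

    Regions, in override order: background (untreated prostate / phantom
    matrix), an optional rectal-wall layer of given thickness at the probe
    surface, an optional surrounding-tissue slab beyond ``surround_depth``,
    and finally the photocoagulation zone, which overrides everything it
    covers.

    ``refractive_mismatch`` is the internal-reflection parameter A of the
    partial-current (Robin) boundary at the probe surface.
    """

    background: OpticalProperties
    zone: Optional[EllipsoidZone] = None
    zone_props: Optional[OpticalProperties] = None
    wall_thickness: float = 0.0
    wall_props: Optional[OpticalProperties] = None
    surround_depth: Optional[float] = None
    surround_props: Optional[OpticalProperties] = None
    refractive_mismatch: float = 2.82
    grid: Grid = field(default_factory=Grid)

    def __post_init__(self) -> None:
        if (self.zone is None) != (self.zone_props is None):
            raise ValueError("zone and zone_props must be provided together")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be >= 0")
        if self.wall_thickness > 0 and self.wall_props is None:
            raise ValueError("wall_props required when wall_thickness > 0")
        if self.surround_depth is not None and self.surround_props is None:
            raise ValueError("surround_props required when surround_depth is set")
        if not self.refractive_mismatch > 0:
            raise ValueError("refractive_mismatch must be > 0")
        if self.zone is not None:
            self._check_zone_in_domain()

    def _check_zone_in_domain(self) -> None:
        z = self.zone
        Lx, Ly, Lz = self.grid.domain
        x0, y0, z0 = z.center
        checks = [
            (abs(x0) + z.a, Lx / 2, "x extent"),
            (abs(y0) + z.b, Ly / 2, "y extent"),
            (z0 + z.a, Lz, "z extent"),
        ]
        for reach, limit, name in checks:
            if reach > limit + 1e-9:
                raise ValueError(
                    f"zone exceeds the domain {name}: reaches {reach:.2f} mm, "
                    f"domain allows {limit:.2f} mm"
                )

    # ----- parameter plumbing used by the inverse solver -------------------

    def with_params(self, **params: float) -> "SceneModel":
        """Return a copy with any of a, b, zone_mua, zone_musp, bg_mua, bg_musp set."""
        scene = self
        zone, zprops, bg = scene.zone, scene.zone_props, scene.background
        if any(k in params for k in ("a", "b")):
            if zone is None:
                raise ValueError("scene has no zone; cannot set shape parameters")
            zone = replace(
                zone,
                a=float(params.get("a", zone.a)),
                b=float(params.get("b", zone.b)),
            )
        if any(k in params for k in ("zone_mua", "zone_musp")):
            if zprops is None:
                raise ValueError("scene has no zone; cannot set zone properties")
            zprops = OpticalProperties(
                float(params.get("zone_mua", zprops.mua)),
                float(params.get("zone_musp", zprops.musp)),
            )
        if any(k in params for k in ("bg_mua", "bg_musp")):
            bg = OpticalProperties(
                float(params.get("bg_mua", bg.mua)),
                float(params.get("bg_musp", bg.musp)),
            )
        known = {"a", "b", "zone_mua", "zone_musp", "bg_mua", "bg_musp"}
        unknown = set(params) - known
        if unknown:
            raise ValueError(f"unknown scene parameters: {sorted(unknown)}")
        return replace(self, zone=zone, zone_props=zprops, background=bg)

    def get_param(self, name: str) -> float:
        if name == "a":
            return self.zone.a
        if name == "b":
            return self.zone.b
        if name == "zone_mua":
            return self.zone_props.mua
        if name == "zone_musp":
            return self.zone_props.musp
        if name == "bg_mua":
            return self.background.mua
        if name == "bg_musp":
            return self.background.musp
        raise ValueError(f"unknown scene parameter {name!r}")

    # ----- rasterization ---------------------------------------------------

    def rasterize(self) -> np.ndarray:
        """Integer region label per voxel (voxel-center membership rule)."""
        X, Y, Z = self.grid.meshgrid()
        labels = np.full(self.grid.shape, LABEL_BACKGROUND, dtype=np.int8)
        if self.wall_thickness > 0:
            labels[Z < self.wall_thickness] = LABEL_WALL
        if self.surround_depth is not None:
            labels[Z >= self.surround_depth] = LABEL_SURROUND
        if self.zone is not None:
            self._check_zone_in_domain()
            labels[self.zone.quadratic_form(X, Y, Z) <= 1.0] = LABEL_ZONE
        return labels

    def zone_occupancy(self, smooth: bool = True) -> Optional[np.ndarray]:
        """Fractional zone membership per voxel in [0, 1].

        With ``smooth`` the crisp ellipsoid indicator is replaced by a ramp of
        total spatial width ~ one voxel across the boundary, which makes the
        predicted intensities differentiable in (a, b) on a fixed grid.
        """
        if self.zone is None:
            return None
        X, Y, Z = self.grid.meshgrid()
        q = self.zone.quadratic_form(X, Y, Z)
        if not smooth:
            return (q <= 1.0).astype(float)
        # approximate signed distance to the ellipsoid surface (exact for
        # spheres, conservative otherwise); ramp width = one voxel
        h = self.grid.spacing
        d = (np.sqrt(q) - 1.0) * min(self.zone.a, self.zone.b)
        return np.clip(0.5 - d / h, 0.0, 1.0)

    def property_volumes(self, smooth: bool = True):
        """(mua, musp) voxel arrays with partial-volume zone boundary."""
        X, Y, Z = self.grid.meshgrid()
        mua = np.full(self.grid.shape, self.background.mua)
        musp = np.full(self.grid.shape, self.background.musp)
        if self.wall_thickness > 0:
            m = Z < self.wall_thickness
            mua[m] = self.wall_props.mua
            musp[m] = self.wall_props.musp
        if self.surround_depth is not None:
            m = Z >= self.surround_depth
            mua[m] = self.surround_props.mua
            musp[m] = self.surround_props.musp
        if self.zone is not None:
            self._check_zone_in_domain()
            f = self.zone_occupancy(smooth=smooth)
            mua = mua * (1.0 - f) + self.zone_props.mua * f
            musp = musp * (1.0 - f) + self.zone_props.musp * f
        return mua, musp


def rasterize_scene(scene: SceneModel) -> np.ndarray:
    """Region-label volume for ``scene`` (voxel-center membership)."""
    return scene.rasterize()
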
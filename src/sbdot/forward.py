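"""CW photon-diffusion forward model on a structured grid.

Solves the steady-state diffusion equation

    -div( D grad Phi ) + mua Phi = q,      D = 1 / (3 (mua + musp))

by a finite-volume discretization with harmonic averaging of D across voxel
faces (which handles the sharp coagulation-zone contrast), a partial-current
(Robin) boundary at the probe plane z = 0 and absorbing (Dirichlet) far
boundaries.  The collimated source fiber is modeled as an isotropic point
source buried one transport mean free path, 1/musp, below the surface.

The detector reading for each source-detector pair is the exitance-
proportional boundary fluence at the detector position; the overall
proportionality constant is absorbed by the per-pair calibration factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import params as prm
from .geometry import Grid, OpticalProperties, ProbeLayout, SceneModel

__all__ = [
    "FluenceField",
    "PredictedFrame",
    "DiffusionForward",
    "solve_fluence",
    "predict_frame",
    "jacobian",
    "semi_infinite_fluence",
]


@dataclass(frozen=True)
class FluenceField:
    """Fluence per voxel (arbitrary units, linear in source power)."""

    values: np.ndarray  # (nx, ny, nz)
    grid: Grid
    source_position: tuple[float, float, float]


@dataclass(frozen=True)
class PredictedFrame:
    """8x8 matrix of predicted intensities, indexed [source, detector]."""

    intensities: np.ndarray
    wavelength_nm: float = 750.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", vals)
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise ValueError("predicted intensities must be positive and finite")


class SolverError(RuntimeError):
    pass


def _trilinear_weights(grid: Grid, point: Sequence[float]):
    """Voxel indices and weights to spread/sample a point on the grid."""
    x, y, z = grid.axes()
    nx, ny, nz = grid.shape
    coords = []
    for axis_vals, p, n in ((x, point[0], nx), (y, point[1], ny), (z, point[2], nz)):
        h = grid.spacing
        t = (p - axis_vals[0]) / h
        if t <= 0.0:
            i0 = i1 = 0
            frac = 0.0
        elif t >= n - 1:
            i0 = i1 = n - 1
            frac = 0.0
        else:
            i0 = int(np.floor(t))
            i1 = i0 + 1
            frac = t - i0
        coords.append((i0, i1, frac))
    idx, wts = [], []
    for ix, wx in ((coords[0][0], 1 - coords[0][2]), (coords[0][1], coords[0][2])):
        for iy, wy in ((coords[1][0], 1 - coords[1][2]), (coords[1][1], coords[1][2])):
            for iz, wz in ((coords[2][0], 1 - coords[2][2]), (coords[2][1], coords[2][2])):
                w = wx * wy * wz
                if w > 0:
                    idx.append((ix, iy, iz))
                    wts.append(w)
    return idx, np.asarray(wts)


class DiffusionForward:
    """Assembled diffusion operator for one scene; factorized once, solved per source.

    Parameters
    ----------
    scene : SceneModel
        Region model carrying the grid and the boundary parameter A.
    layout : ProbeLayout, optional
        Needed only for :meth:`predict`.
    smooth_boundary : bool
        Use partial-volume zone occupancy (default) instead of the crisp
        voxel-center mask.
    """

    def __init__(self, scene: SceneModel, layout: Optional[ProbeLayout] = None,
                 smooth_boundary: bool = True):
        self.scene = scene
        self.layout = layout
        self.grid = scene.grid
        self.mua, self.musp = scene.property_volumes(smooth=smooth_boundary)
        self._assemble()
        self._factor = None

    # ----- discretization --------------------------------------------------

    def _assemble(self) -> None:
        g = self.grid
        nx, ny, nz = g.shape
        h = g.spacing
        area_over_h = h  # (h*h)/h for a cubic voxel
        D = 1.0 / (3.0 * (self.mua + self.musp))
        self._D = D
        N = nx * ny * nz
        diag = self.mua.ravel() * h**3

        rows, cols, vals = [], [], []
        idx = np.arange(N).reshape(nx, ny, nz)

        def add_faces(sl_lo, sl_hi):
            Dlo, Dhi = D[sl_lo], D[sl_hi]
            G = (2.0 * Dlo * Dhi / (Dlo + Dhi)) * area_over_h
            ilo, ihi = idx[sl_lo].ravel(), idx[sl_hi].ravel()
            Gf = G.ravel()
            rows.extend((ilo, ihi))
            cols.extend((ihi, ilo))
            vals.extend((-Gf, -Gf))
            np.add.at(diag, ilo, Gf)
            np.add.at(diag, ihi, Gf)

        add_faces((slice(None, -1), slice(None), slice(None)),
                  (slice(1, None), slice(None), slice(None)))
        add_faces((slice(None), slice(None, -1), slice(None)),
                  (slice(None), slice(1, None), slice(None)))
        add_faces((slice(None), slice(None), slice(None, -1)),
                  (slice(None), slice(None), slice(1, None)))

        # Robin (partial-current) boundary at z = 0:
        # outward flux per area = Phi_center / (2A + h/(2D)).
        A = self.scene.refractive_mismatch
        D0 = D[:, :, 0]
        robin = (h * h) / (2.0 * A + h / (2.0 * D0))
        np.add.at(diag, idx[:, :, 0].ravel(), robin.ravel())
        self._robin_coeff = 1.0 / (2.0 * A + h / (2.0 * D0))

        # Dirichlet (Phi = 0) ghost faces on the padded far boundaries.
        for sl in (
            (slice(0, 1), slice(None), slice(None)),
            (slice(-1, None), slice(None), slice(None)),
            (slice(None), slice(0, 1), slice(None)),
            (slice(None), slice(-1, None), slice(None)),
            (slice(None), slice(None), slice(-1, None)),
        ):
            np.add.at(diag, idx[sl].ravel(), (2.0 * D[sl] * area_over_h).ravel())

        rows.append(np.arange(N))
        cols.append(np.arange(N))
        vals.append(diag)
        self._matrix = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        )

    # Direct factorization wins for small systems (reused across 8 sources);
    # Jacobi-preconditioned CG scales far better on fine grids.
    _DIRECT_MAX_N = 8000

    def _factorize(self):
        if self._factor is None:
            try:
                self._factor = spla.splu(self._matrix, permc_spec="MMD_AT_PLUS_A",
                                         options={"SymmetricMode": True})
            except RuntimeError as exc:  # singular matrix
                raise SolverError(f"diffusion operator factorization failed: {exc}") from exc
        return self._factor

    def _solve_vec(self, b: np.ndarray) -> np.ndarray:
        if self._matrix.shape[0] <= self._DIRECT_MAX_N:
            return self._factorize().solve(b)
        if not hasattr(self, "_precond"):
            dinv = 1.0 / self._matrix.diagonal()
            self._precond = spla.LinearOperator(self._matrix.shape,
                                                matvec=lambda v: dinv * v)
        phi, info = spla.cg(self._matrix, b, rtol=1e-10, atol=0.0,
                            maxiter=5000, M=self._precond)
        if info != 0:
            res = np.linalg.norm(self._matrix @ phi - b) / max(np.linalg.norm(b), 1e-300)
            raise SolverError(f"CG did not converge (info={info}, relative residual {res:.2e})")
        return phi

    # ----- solves ----------------------------------------------------------

    def _source_vector(self, position_xy: Sequence[float], power: float = 1.0) -> np.ndarray:
        depth = 1.0 / self.scene.background.musp
        point = (position_xy[0], position_xy[1], depth)
        q = np.zeros(self.grid.shape)
        idx, wts = _trilinear_weights(self.grid, point)
        for (i, j, k), w in zip(idx, wts):
            q[i, j, k] += power * w
        return q.ravel()

    def solve(self, source_xy: Sequence[float], power: float = 1.0) -> FluenceField:
        b = self._source_vector(source_xy, power)
        phi = self._solve_vec(b)
        rnorm = np.linalg.norm(self._matrix @ phi - b) / max(np.linalg.norm(b), 1e-300)
        if not np.all(np.isfinite(phi)) or rnorm > 1e-6:
            raise SolverError(f"linear solve did not converge (relative residual {rnorm:.2e})")
        depth = 1.0 / self.scene.background.musp
        return FluenceField(phi.reshape(self.grid.shape), self.grid,
                            (source_xy[0], source_xy[1], depth))

    def sample_boundary(self, phi: np.ndarray, position_xy: Sequence[float]) -> float:
        """Exitance-proportional reading at a detector position on z = 0.

        Interpolation is done on log(exitance): the field decays near-
        exponentially with lateral distance, so linear interpolation of the
        raw values biases off-grid detectors high.
        """
        h = self.grid.spacing
        point = (position_xy[0], position_xy[1], h / 2.0)
        idx, wts = _trilinear_weights(self.grid, point)
        log_val = 0.0
        for (i, j, k), w in zip(idx, wts):
            log_val += w * np.log(max(phi[i, j, k] * self._robin_coeff[i, j], 1e-300))
        return float(np.exp(log_val))

    def predict(self, layout: Optional[ProbeLayout] = None,
                source_powers: Optional[Sequence[float]] = None) -> np.ndarray:
        layout = layout or self.layout
        if layout is None:
            raise ValueError("a ProbeLayout is required for prediction")
        n_s, n_d = len(layout.sources), len(layout.detectors)
        out = np.empty((n_s, n_d))
        for si, s in enumerate(layout.sources):
            p = 1.0 if source_powers is None else source_powers[si]
            field = self.solve(s, power=p)
            for di, d in enumerate(layout.detectors):
                out[si, di] = self.sample_boundary(field.values, d)
        if np.any(out <= 0) or not np.all(np.isfinite(out)):
            raise SolverError("nonpositive or nonfinite predicted intensity")
        return out


def solve_fluence(scene: SceneModel, source_position: Sequence[float],
                  smooth_boundary: bool = True) -> FluenceField:
    """Fluence field for a single source at (x, y) on the probe plane."""
    return DiffusionForward(scene, smooth_boundary=smooth_boundary).solve(source_position)


def predict_frame(scene: SceneModel, layout: ProbeLayout,
                  wavelength_nm: float = 750.0,
                  smooth_boundary: bool = True) -> PredictedFrame:
    """Predicted 8x8 intensity matrix for all source-detector pairs."""
    op = DiffusionForward(scene, layout, smooth_boundary=smooth_boundary)
    return PredictedFrame(op.predict(), wavelength_nm=wavelength_nm)


def jacobian(scene: SceneModel, layout: ProbeLayout,
             param_names: Sequence[str],
             base_prediction: Optional[np.ndarray] = None,
             scheme: str = "forward",
             smooth_boundary: bool = True) -> np.ndarray:
    """Finite-difference Jacobian of log-intensities w.r.t. scaled parameters.

    Returns a (64, n_params) matrix with columns ordered as ``param_names``.
    Shape parameters use a grid-linked step, optical properties a 1e-3
    relative step in log space (see :mod:`sbdot.params`).
    """
    if base_prediction is None:
        base_prediction = DiffusionForward(scene, layout, smooth_boundary).predict()
    log_base = np.log(base_prediction).ravel()
    h = scene.grid.spacing
    cols = []
    base_occ = scene.zone_occupancy(smooth=smooth_boundary)
    for name in param_names:
        u0 = prm.scale(name, scene.get_param(name))
        du = prm.fd_step(name, h)
        if scene.zone is not None and name in ("zone_mua", "zone_musp"):
            occ = scene.zone_occupancy(smooth=smooth_boundary)
            if occ is not None and not np.any(occ > 0):
                cols.append(np.zeros_like(log_base))  # provably insensitive
                continue

        def predict_at(u: float) -> np.ndarray:
            pert = scene.with_params(**{name: prm.unscale(name, u)})
            if prm.is_shape(name):
                occ = pert.zone_occupancy(smooth=smooth_boundary)
                if np.array_equal(occ, base_occ):
                    raise SolverError(
                        f"finite-difference step for {name!r} left the rasterized zone "
                        f"unchanged; use a finer grid or a larger step"
                    )
            return DiffusionForward(pert, layout, smooth_boundary).predict()

        if scheme == "forward":
            try:
                col = (np.log(predict_at(u0 + du)).ravel() - log_base) / du
            except ValueError:
                # forward step leaves the feasible region (e.g. a -> z0); step back
                col = (log_base - np.log(predict_at(u0 - du)).ravel()) / du
        elif scheme == "central":
            try:
                hi = np.log(predict_at(u0 + du)).ravel()
            except ValueError:
                hi = None
            try:
                lo = np.log(predict_at(u0 - du)).ravel()
            except ValueError:
                lo = None
            if hi is not None and lo is not None:
                col = (hi - lo) / (2 * du)
            elif hi is not None:
                col = (hi - log_base) / du
            elif lo is not None:
                col = (log_base - lo) / du
            else:
                raise SolverError(f"no feasible finite-difference step for {name!r}")
        else:
            raise ValueError(f"unknown difference scheme {scheme!r}")
        cols.append(col)
    return np.column_stack(cols)


def semi_infinite_fluence(props: OpticalProperties, rho: float, z: float,
                          refractive_mismatch: float = 2.82,
                          power: float = 1.0) -> float:
    """Closed-form CW fluence in a homogeneous half-space.

    Extrapolated-boundary image-source Green's function: an isotropic point
    source at depth z0 = 1/musp and a negative image mirrored about the
    extrapolation plane z = -zb, zb = 2 A D.
    """
    D = props.diffusion
    mueff = props.mueff
    z0 = 1.0 / props.musp
    zb = 2.0 * refractive_mismatch * D
    r1 = np.sqrt(rho**2 + (z - z0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z0 + 2 * zb) ** 2)
    return power / (4.0 * np.pi * D) * (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2)
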
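"""Shape-based reconstruction: fit an ellipsoidal coagulation zone to one frame.

The inverse problem is a low-dimensional regularized nonlinear least-squares
fit.  For a calibrated measurement frame m(s, d) and the diffusion forward
model p(s, d; theta) the cost is

    C(theta) = sum_valid w_i (log m_i - log p_i)^2 + tau ||theta - theta_0||^2

over the internally scaled parameter vector theta (lengths in mm/10,
properties in log space).  Log residuals make the multiplicative instrument
noise and calibration structure approximately homoscedastic.  Minimization
uses Levenberg-Marquardt with box-bound projection; parameter uncertainties
come from the Gauss-Newton Hessian and, independently, from a channel
bootstrap over the 64 source-detector pairs.

The ellipsoid center is fixed at the known treatment-fiber position by
default; fitting it can be enabled through the config.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import params as prm
from .forward import DiffusionForward, jacobian as forward_jacobian
from .frames import MeasurementFrame
from .geometry import ProbeLayout, SceneModel

__all__ = [
    "ReconstructionConfig",
    "ShapeFit",
    "ShapeFitResults",
    "fit",
    "hessian_errors",
    "bootstrap_uncertainty",
    "sensitivity_sweep",
    "combine_wavelengths",
]

BOUND_TOL = 1e-6  # scaled-parameter distance that counts as "on the bound"


@dataclass
class ReconstructionConfig:
    """Everything the fit needs besides the data.

    Default fitted set is the transverse and longitudinal semi-axes plus the
    zone optical properties.  Bounds: a in [1, 15] mm; the longitudinal full
    length 2b is bounded by the optical-window length (b in [1, window/2]);
    properties within a factor 10 of their initial values.
    """

    fit_params: Tuple[str, ...] = ("a", "b", "zone_mua", "zone_musp")
    initial: Dict[str, float] = field(default_factory=dict)
    fixed: Dict[str, float] = field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    a_bounds: Tuple[float, float] = (1.0, 15.0)
    property_bound_factor: float = 10.0
    lm_lambda0: float = 1e-2
    lm_up: float = 10.0
    lm_down: float = 3.0
    lm_lambda_max: float = 1e10
    max_step: float = 0.5         # cap on the scaled-parameter step per iteration
    staged: bool = True           # shape-only pre-fit before the joint fit
    jacobian_scheme: str = "central"  # central differences: the forward-only
                                      # scheme biases the fixed point by ~du/2
    tikhonov: float = 1e-4
    tol_cost: float = 1e-6
    tol_cost_abs: float = 1e-14   # noiseless data: cost decays to 0 geometrically
    tol_step: float = 1e-4        # scaled units: 1 um in lengths, 0.01% in properties
    max_iter: int = 50
    seed: int = 0

    def validate(self) -> None:
        for p in self.fit_params:
            if p not in prm.ALL_PARAMS:
                raise ValueError(f"unknown fit parameter {p!r}")
        if self.tol_cost <= 0 or self.tol_step <= 0:
            raise ValueError("convergence tolerances must be > 0")

    def resolve_bounds(self, name: str, init_value: float,
                       window_length: float) -> Tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name == "a":
            return self.a_bounds
        if name == "b":
            return (1.0, window_length / 2.0)
        f = self.property_bound_factor
        return (init_value / f, init_value * f)


class ShapeFit:
    """Model object binding one calibrated frame to a scene template.

    Statsmodels-style usage::

        model = ShapeFit(frame, scene_template, layout, config)
        res = model.fit()
        print(res.summary())
        sd = res.bootstrap(n_rep=50, seed=1)
    """

    def __init__(self, frame: MeasurementFrame, scene_template: SceneModel,
                 layout: ProbeLayout, config: Optional[ReconstructionConfig] = None):
        if frame.n_valid == 0:
            raise ValueError("frame has no valid channels")
        config = config or ReconstructionConfig()
        config.validate()
        self.frame = frame
        self.layout = layout
        self.config = config

        scene = scene_template
        if config.fixed:
            scene = scene.with_params(**config.fixed)
        self.scene_template = scene

        self.param_names = tuple(config.fit_params)
        if frame.n_valid <= len(self.param_names):
            warnings.warn("fewer valid channels than parameters + 1; fit is underdetermined")

        init_phys = {}
        for name in self.param_names:
            init_phys[name] = float(config.initial.get(name, scene.get_param(name)))
        self._theta0 = np.array([prm.scale(n, init_phys[n]) for n in self.param_names])
        lo, hi = [], []
        for name in self.param_names:
            b = config.resolve_bounds(name, init_phys[name], layout.window_length)
            if name == "a" and scene.zone is not None:
                # the zone may not penetrate the probe surface: a <= z0
                b = (b[0], min(b[1], scene.zone.center[2]))
            lo.append(prm.scale(name, b[0]))
            hi.append(prm.scale(name, b[1]))
        self._lb, self._ub = np.array(lo), np.array(hi)
        if np.any(self._theta0 < self._lb - 1e-12) or np.any(self._theta0 > self._ub + 1e-12):
            raise ValueError("initial estimates must lie within bounds")
        self._theta0 = np.clip(self._theta0, self._lb, self._ub)
        self._log_m = np.log(frame.intensities[frame.mask])
        self._mask_flat = frame.mask.ravel()

    # ----- plumbing --------------------------------------------------------

    def scene_at(self, theta: np.ndarray) -> SceneModel:
        phys = {n: prm.unscale(n, u) for n, u in zip(self.param_names, theta)}
        return self.scene_template.with_params(**phys)

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        return DiffusionForward(self.scene_at(theta), self.layout).predict()

    def _residuals(self, theta: np.ndarray, sw: np.ndarray,
                   prediction: Optional[np.ndarray] = None) -> np.ndarray:
        pred = self._predict(theta) if prediction is None else prediction
        return sw * (self._log_m - np.log(pred[self.frame.mask]))

    def _cost(self, r: np.ndarray, theta: np.ndarray) -> float:
        reg = self.config.tikhonov * np.sum((theta - self._theta0) ** 2)
        return float(np.dot(r, r) + reg)

    def _jacobian(self, theta: np.ndarray, sw: np.ndarray,
                  base_prediction: np.ndarray) -> np.ndarray:
        J = forward_jacobian(self.scene_at(theta), self.layout, self.param_names,
                             base_prediction=base_prediction,
                             scheme=self.config.jacobian_scheme)
        return -sw[:, None] * J[self._mask_flat, :]

    # ----- the Levenberg-Marquardt loop ------------------------------------

    def fit(self, start: Optional[Dict[str, float]] = None,
            weights: Optional[np.ndarray] = None) -> "ShapeFitResults":
        """Run the regularized fit.  Deterministic for a fixed config.

        By default the fit is staged: a robust shape-only pre-fit (optical
        properties clamped at their initial estimates) locates the boundary,
        then the joint shape + property fit refines from there.  Staging is
        skipped for warm starts (``start`` given) and when the fitted set
        does not mix shape and property parameters.

        ``weights`` (8x8, e.g. bootstrap channel counts) multiply squared
        residuals; ``start`` overrides the configured initial estimates.
        """
        cfg = self.config
        shape_set = [p for p in self.param_names if p in prm.SHAPE_PARAMS]
        prop_set = [p for p in self.param_names if p not in prm.SHAPE_PARAMS]
        if cfg.staged and start is None and shape_set and prop_set:
            pre_cfg = ReconstructionConfig(**{**cfg.__dict__})
            pre_cfg.fit_params = tuple(shape_set)
            pre_cfg.staged = False
            pre_cfg.initial = dict(cfg.initial)
            pre = ShapeFit(self.frame, self.scene_template, self.layout, pre_cfg)
            pre_res = pre._fit_core(None, weights)
            start = {p: pre_res.params[p] for p in shape_set}
            res = self._fit_core(start, weights)
            res.n_iter += pre_res.n_iter
            return res
        return self._fit_core(start, weights)

    def _fit_core(self, start: Optional[Dict[str, float]] = None,
                  weights: Optional[np.ndarray] = None) -> "ShapeFitResults":
        cfg = self.config
        if weights is None:
            sw = np.ones(self.frame.n_valid)
        else:
            w = np.asarray(weights, dtype=float)[self.frame.mask]
            if np.any(w < 0):
                raise ValueError("weights must be >= 0")
            sw = np.sqrt(w)

        theta = self._theta0.copy()
        if start is not None:
            for i, n in enumerate(self.param_names):
                if n in start:
                    theta[i] = prm.scale(n, start[n])
            theta = np.clip(theta, self._lb, self._ub)

        tau = cfg.tikhonov
        lam = cfg.lm_lambda0
        pred = self._predict(theta)
        r = self._residuals(theta, sw, prediction=pred)
        cost = self._cost(r, theta)
        cost_path = [cost]
        converged = False
        identifiable = True
        n_iter = 0
        J = self._jacobian(theta, sw, pred)

        for n_iter in range(1, cfg.max_iter + 1):
            col_norms = np.linalg.norm(J, axis=0)
            if np.any(col_norms < 1e-12):
                identifiable = False
            H = J.T @ J + tau * np.eye(len(theta))
            g = J.T @ r + tau * (theta - self._theta0)
            accepted = False
            while lam <= cfg.lm_lambda_max:
                try:
                    step = np.linalg.solve(H + lam * np.eye(len(theta)), -g)
                except np.linalg.LinAlgError:
                    lam *= cfg.lm_up
                    continue
                overshoot = np.max(np.abs(step))
                if overshoot > cfg.max_step:
                    step *= cfg.max_step / overshoot
                theta_new = np.clip(theta + step, self._lb, self._ub)
                pred_new = self._predict(theta_new)
                r_new = self._residuals(theta_new, sw, prediction=pred_new)
                cost_new = self._cost(r_new, theta_new)
                if cost_new < cost:
                    accepted = True
                    break
                lam *= cfg.lm_up
            if not accepted:
                converged = True  # damping exhausted: at a (local) minimum
                break
            actual_step = theta_new - theta
            rel_drop = (cost - cost_new) / max(cost, 1e-300)
            theta, r, cost, pred = theta_new, r_new, cost_new, pred_new
            cost_path.append(cost)
            lam = max(lam / cfg.lm_down, 1e-14)
            J = self._jacobian(theta, sw, pred)
            if (rel_drop < cfg.tol_cost or cost < cfg.tol_cost_abs
                    or np.max(np.abs(actual_step)) < cfg.tol_step):
                converged = True
                break

        se, cov, identifiable_h = hessian_errors(
            self, theta, J, r, tikhonov=tau)
        identifiable = identifiable and identifiable_h
        bound_hits = {
            n: bool(theta[i] - self._lb[i] < BOUND_TOL or self._ub[i] - theta[i] < BOUND_TOL)
            for i, n in enumerate(self.param_names)
        }
        params = {n: prm.unscale(n, u) for n, u in zip(self.param_names, theta)}
        return ShapeFitResults(
            model=self,
            params=params,
            bse=dict(zip(self.param_names, se)),
            cov=cov,
            resid_norm=float(np.linalg.norm(r)),
            n_iter=n_iter,
            converged=converged,
            identifiable=identifiable,
            bound_hits=bound_hits,
            cost_path=tuple(cost_path),
            theta_scaled=theta,
        )

    def bootstrap(self, n_rep: int = 50, seed: int = 0,
                  base_result: Optional["ShapeFitResults"] = None,
                  with_replacement: bool = True,
                  subset_size: Optional[int] = None) -> pd.DataFrame:
        """Channel-bootstrap refits; returns a DataFrame of fitted parameters.

        Each replicate resamples the 64 source-detector pairs with
        replacement (duplicates weight the residuals) and refits, warm-started
        from the full-data result.  ``with_replacement=False`` draws subsets
        of ``subset_size`` pairs instead.
        """
        rng = np.random.default_rng(seed)
        if base_result is None:
            base_result = self.fit()
        n_params = len(self.param_names)
        rows = []
        for _ in range(n_rep):
            for attempt in range(10):
                if with_replacement:
                    pick = rng.integers(0, 64, size=64)
                    w = np.bincount(pick, minlength=64).reshape(8, 8).astype(float)
                else:
                    k = subset_size or 48
                    pick = rng.choice(64, size=k, replace=False)
                    w = np.zeros(64)
                    w[pick] = 1.0
                    w = w.reshape(8, 8)
                n_eff = int(np.count_nonzero(w.ravel()[self._mask_flat]))
                if n_eff >= n_params + 1:
                    break
            else:
                raise RuntimeError("could not draw a resample with enough valid channels")
            res = self.fit(start=base_result.params, weights=w)
            rows.append(res.params)
        return pd.DataFrame(rows)


def hessian_errors(model: ShapeFit, theta: np.ndarray, J: np.ndarray,
                   r: np.ndarray, tikhonov: float = 0.0):
    """Standard errors and covariance from the Gauss-Newton Hessian.

    cov = s^2 (J^T J + tau I)^-1 with s^2 = RSS / dof, mapped back to
    physical units through the parameter scaling.  Returns
    (standard_errors, covariance, identifiable).
    """
    n_params = len(theta)
    dof = max(r.size - n_params, 1)
    s2 = float(np.dot(r, r)) / dof
    H = J.T @ J + tikhonov * np.eye(n_params)
    dead = np.linalg.norm(J, axis=0) < 1e-10
    identifiable = not np.any(dead)
    try:
        cov_scaled = s2 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return (np.full(n_params, np.inf),
                np.full((n_params, n_params), np.inf), False)
    if np.linalg.cond(J.T @ J) > 1e12 and tikhonov == 0:
        identifiable = False
    scale_vec = np.array([prm.d_physical_d_scaled(n, u)
                          for n, u in zip(model.param_names, theta)])
    cov = cov_scaled * np.outer(scale_vec, scale_vec)
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # a parameter the data provably cannot constrain has no finite error
    se[dead] = np.inf
    cov[dead, :] = np.inf
    cov[:, dead] = np.inf
    return se, cov, identifiable


@dataclass
class ShapeFitResults:
    """Fitted parameters, uncertainties and diagnostics for one frame."""

    model: ShapeFit
    params: Dict[str, float]
    bse: Dict[str, float]
    cov: np.ndarray
    resid_norm: float
    n_iter: int
    converged: bool
    identifiable: bool
    bound_hits: Dict[str, bool]
    cost_path: Tuple[float, ...]
    theta_scaled: np.ndarray

    @property
    def param_names(self) -> Tuple[str, ...]:
        return self.model.param_names

    def cov_params(self) -> pd.DataFrame:
        names = list(self.param_names)
        return pd.DataFrame(self.cov, index=names, columns=names)

    @property
    def transverse_radius(self) -> float:
        return self.params["a"]

    @property
    def longitudinal_size(self) -> float:
        """Fitted longitudinal full length 2b (mm)."""
        return 2.0 * self.params["b"]

    def distance_to_probe(self) -> float:
        scene = self.model.scene_at(self.theta_scaled)
        return scene.zone.distance_to_probe

    def bootstrap(self, n_rep: int = 50, seed: int = 0, **kw) -> Dict[str, float]:
        """Bootstrap SD per fitted parameter (see :meth:`ShapeFit.bootstrap`)."""
        df = self.model.bootstrap(n_rep=n_rep, seed=seed, base_result=self, **kw)
        return {n: float(df[n].std(ddof=1)) for n in self.param_names}

    def summary(self) -> str:
        lines = [
            "Shape-based DOT reconstruction",
            "=" * 46,
            f"channels used: {self.model.frame.n_valid}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"residual norm (log-intensity): {self.resid_norm:.4g}",
            f"identifiable: {self.identifiable}",
            "-" * 46,
            f"{'parameter':<12}{'value':>10}{'std err':>10}{'at bound':>10}",
        ]
        units = {"a": "mm", "b": "mm"}
        for n in self.param_names:
            u = units.get(n, "mm^-1")
            lines.append(
                f"{n:<12}{self.params[n]:>10.4g}{self.bse[n]:>10.3g}"
                f"{'yes' if self.bound_hits[n] else 'no':>10}  [{u}]"
            )
        if "a" in self.params:
            lines.append("-" * 46)
            lines.append(
                f"boundary-to-probe distance: {self.distance_to_probe():.2f} mm"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "params": self.params,
            "standard_errors": self.bse,
            "covariance_row_major": [float(v) for v in np.asarray(self.cov).ravel()],
            "param_order": list(self.param_names),
            "residual_norm": self.resid_norm,
            "iterations": self.n_iter,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "bound_hits": self.bound_hits,
            "config": {k: v for k, v in asdict(self.model.config).items()},
        }
        return json.dumps(payload, indent=2)


# ----- functional op surface -----------------------------------------------


def fit(frame: MeasurementFrame, scene_template: SceneModel, layout: ProbeLayout,
        config: Optional[ReconstructionConfig] = None) -> ShapeFitResults:
    """Fit ellipsoid shape and optical properties to one calibrated frame."""
    return ShapeFit(frame, scene_template, layout, config).fit()


def bootstrap_uncertainty(frame: MeasurementFrame, scene_template: SceneModel,
                          layout: ProbeLayout, config: Optional[ReconstructionConfig] = None,
                          n_rep: int = 50, seed: int = 0) -> Dict[str, float]:
    """Bootstrap SD of each fitted parameter over channel resamples."""
    model = ShapeFit(frame, scene_template, layout, config)
    base = model.fit()
    return base.bootstrap(n_rep=n_rep, seed=seed)


def sensitivity_sweep(frame: MeasurementFrame, scene_template: SceneModel,
                      layout: ProbeLayout, base_config: ReconstructionConfig,
                      initial_grids: Optional[Dict[str, Sequence[float]]] = None,
                      fixed_offset_grids: Optional[Dict[str, Sequence[float]]] = None,
                      ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Grid sweep over initial estimates and/or fixed-property offsets.

    ``initial_grids`` maps parameter name -> absolute initial values;
    ``fixed_offset_grids`` maps parameter name -> fractional offsets applied
    to the template's (true) value while the parameter is held fixed.
    Returns a tidy table of results and summary statistics of the fitted
    transverse radius.
    """
    initial_grids = initial_grids or {}
    fixed_offset_grids = fixed_offset_grids or {}
    init_names = list(initial_grids)
    off_names = list(fixed_offset_grids)
    rows = []
    for init_vals in itertools.product(*(initial_grids[n] for n in init_names)) or [()]:
        for offsets in itertools.product(*(fixed_offset_grids[n] for n in off_names)) or [()]:
            cfg = ReconstructionConfig(**asdict(base_config))
            cfg.initial = dict(base_config.initial)
            cfg.fixed = dict(base_config.fixed)
            for n, v in zip(init_names, init_vals):
                cfg.initial[n] = v
            for n, f in zip(off_names, offsets):
                cfg.fixed[n] = scene_template.get_param(n) * (1.0 + f)
                cfg.fit_params = tuple(p for p in cfg.fit_params if p not in cfg.fixed)
            res = ShapeFit(frame, scene_template, layout, cfg).fit()
            row = {f"init_{n}": v for n, v in zip(init_names, init_vals)}
            row.update({f"offset_{n}": f for n, f in zip(off_names, offsets)})
            row.update({f"fit_{k}": v for k, v in res.params.items()})
            row["converged"] = res.converged
            rows.append(row)
    table = pd.DataFrame(rows)
    radii = table["fit_a"]
    summary = {
        "mean_a": float(radii.mean()),
        "sd_a": float(radii.std(ddof=1)) if len(radii) > 1 else 0.0,
        "max_abs_dev_a": float((radii - radii.mean()).abs().max()),
    }
    return table, summary


def combine_wavelengths(results: List[ShapeFitResults]):
    """Pool shape parameters across wavelengths (unweighted mean +/- SD).

    Optical properties remain per-wavelength.  Non-converged members are
    excluded with a warning.
    """
    if not results:
        raise ValueError("no results to combine")
    usable = [r for r in results if r.converged]
    if len(usable) < len(results):
        warnings.warn(f"excluding {len(results) - len(usable)} non-converged result(s)")
    if not usable:
        raise ValueError("no converged results to combine")
    a = np.array([r.params["a"] for r in usable])
    b = np.array([r.params.get("b", np.nan) for r in usable])
    pooled = {
        "a_mean": float(a.mean()),
        "a_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "b_mean": float(np.nanmean(b)),
        "b_sd": float(np.nanstd(b, ddof=1)) if len(b) > 1 else 0.0,
        "n": len(usable),
        "per_wavelength": {
            r.model.frame.wavelength_nm: {k: v for k, v in r.params.items()
                                          if k not in ("a", "b")}
            for r in usable
        },
    }
    return pooled
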
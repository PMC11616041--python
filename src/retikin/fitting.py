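"""FSD-weighted nonlinear least-squares fitting of the composite curve.

Seven quantities are adjusted: the exchange/loss coefficients L(5,4),
L(6,5), L(5,6), L(7,5), L(5,7), L(0,6) and the absorption delay DT(3).
L(8,5) is eliminated by the structural loss-partition constraint
R(8,5) = R(0,6), which holds exactly at every iterate.  Optimization is
over the natural logs of the parameters: they span four orders of
magnitude and must stay positive, and on the log scale the Gauss-Newton
covariance diagonal is directly the squared fractional standard
deviation (FSD) of each estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, UnidentifiableParameterError, ValidationError
from .model import ModelParameters, simulate_tracer
from .supersubject import CompositeDataset

__all__ = ["FIT_PARAMETER_NAMES", "FitResult", "fit_composite", "parameter_uncertainty"]

#: fit parameters, in optimization order
FIT_PARAMETER_NAMES: tuple[str, ...] = (
    "L(5,4)", "L(6,5)", "L(5,6)", "L(7,5)", "L(5,7)", "L(0,6)", "DT(3)",
)

_RATE_KEYS = {
    "L(5,4)": (5, 4), "L(6,5)": (6, 5), "L(5,6)": (5, 6),
    "L(7,5)": (7, 5), "L(5,7)": (5, 7), "L(0,6)": (0, 6),
}


def _params_to_theta(params: ModelParameters) -> np.ndarray:
    vals = [params.l[_RATE_KEYS[n]] for n in FIT_PARAMETER_NAMES[:-1]] + [params.dt3]
    if min(vals) <= 0:
        raise ValidationError("all adjustable parameters must be > 0 for log fitting")
    return np.log(vals)


def _theta_to_params(theta: np.ndarray, template: ModelParameters) -> ModelParameters:
    vals = np.exp(theta)
    updates = {n: v for n, v in zip(FIT_PARAMETER_NAMES[:-1], vals[:-1])}
    return template.replace(dt3=float(vals[-1]), **updates)


@dataclass
class FitResult:
    """Converged fit with uncertainty and diagnostics."""

    params: ModelParameters
    objective: float                     # weighted residual sum of squares
    param_fsd: Mapping[str, float]
    residuals: np.ndarray                # weighted, per time point
    n_iterations: int
    gradient_norm: float
    success: bool
    message: str
    covariance_log: np.ndarray | None = None
    restart_objectives: tuple[float, ...] = ()

    def report_frame(self):
        """Parameter/value/FSD table in the conventional reporting layout."""
        import pandas as pd

        d = self.params.to_dict()
        rows = []
        for name, value in d.items():
            rows.append((name, value, self.param_fsd.get(name, np.nan)))
        return pd.DataFrame(rows, columns=["parameter", "value", "fsd"])


def _residual_fn(dataset: CompositeDataset, template: ModelParameters, weighting: str):
    if weighting not in ("observed", "model"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    times = dataset.times
    obs = dataset.gm_fdp
    fsd = dataset.fsd_weight

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            params = _theta_to_params(theta, template)
            pred = simulate_tracer(params, times).fdp
        except Exception:
            return np.full(times.size, 1e6)
        if weighting == "observed":
            denom = fsd * obs
        elif weighting == "model":
            denom = fsd * np.maximum(pred, 1e-300)
        else:
            raise ValidationError(f"unknown weighting {weighting!r}")
        return (obs - pred) / denom

    return residuals


def fit_composite(
    dataset: CompositeDataset,
    init: ModelParameters,
    *,
    weighting: str = "observed",
    n_restarts: int = 5,
    restart_jitter: float = 1.5,
    seed: int = 0,
    max_iterations: int = 500,
    ftol: float = 1e-10,
    gtol: float = 1e-8,
) -> FitResult:
    """Fit the adjustable parameters to a composite FDp dataset.

    Minimizes sum(((obs - model)/(FSD * obs))^2) over the log-transformed
    adjustable parameters, with L(8,5) recomputed from the loss-partition
    constraint at every evaluation.  ``n_restarts`` seeded multiplicative
    jitters of the initial values guard against local minima; the best
    objective wins (ties broken by restart order).
    """
    if dataset.times.size < 8:
        raise ValidationError(
            "need >= 8 informative time points spanning absorption and terminal phases"
        )
    if not init.constraint_mode:
        warnings.warn("fitting without the loss-partition constraint; L(8,5) stays fixed")

    fun = _residual_fn(dataset, init, weighting)
    theta0 = _params_to_theta(init)
    rng = np.random.default_rng(seed)

    # physical box on the log scale: rates within [1e-7, 1e4] /d, the
    # absorption delay within [1e-5, 20] d
    lb = np.log(np.array([1e-7] * 6 + [1e-5]))
    ub = np.log(np.array([1e4] * 6 + [20.0]))
    theta0 = np.clip(theta0, lb + 1e-9, ub - 1e-9)

    best = None
    restart_objs = []
    for restart in range(max(1, n_restarts)):
        start = theta0 if restart == 0 else np.clip(
            theta0 + rng.uniform(-np.log(restart_jitter), np.log(restart_jitter),
                                 theta0.size),
            lb + 1e-9, ub - 1e-9,
        )
        try:
            res = least_squares(
                fun, start, method="trf", bounds=(lb, ub),
                ftol=ftol, xtol=1e-12, gtol=gtol,
                max_nfev=max_iterations * (theta0.size + 1),
            )
        except Exception:
            continue
        obj = float(np.sum(res.fun**2))
        restart_objs.append(obj)
        if np.isfinite(obj) and (best is None or obj < best[0] * (1 - 1e-12)):
            best = (obj, res)

    if best is None:
        raise ConvergenceError("all restarts failed", best=init)
    obj, res = best
    if not res.success:
        raise ConvergenceError(
            f"fit did not converge: {res.message}",
            best=_theta_to_params(res.x, init),
        )
    at_bound = [
        FIT_PARAMETER_NAMES[i] for i in range(res.x.size)
        if res.x[i] <= lb[i] + 1e-6 or res.x[i] >= ub[i] - 1e-6
    ]
    if at_bound:
        warnings.warn(f"parameter(s) at bounds: {at_bound}")
    params = _theta_to_params(res.x, init)
    grad = res.grad if res.grad is not None else res.jac.T @ res.fun
    fit = FitResult(
        params=params,
        objective=obj,
        param_fsd={},
        residuals=res.fun,
        n_iterations=int(res.nfev),
        gradient_norm=float(np.linalg.norm(grad)),
        success=True,
        message=str(res.message),
        restart_objectives=tuple(restart_objs),
    )
    try:
        fsd, cov = _fsd_from_jacobian(res.jac, res.fun, dataset.times.size)
    except UnidentifiableParameterError as exc:
        warnings.warn(f"parameter uncertainty unavailable: {exc}")
        fsd, cov = {name: float("inf") for name in exc.parameters}, None
    fit.param_fsd = fsd
    fit.covariance_log = cov
    return fit


def _fsd_from_jacobian(jac: np.ndarray, resid: np.ndarray, n_obs: int):
    """Parameter FSDs from the Gauss-Newton covariance on the log scale.

    cov = s^2 (J^T J)^-1 with s^2 = WRSS/(n-p); since the parameters are
    log-transformed, sqrt(diag(cov)) is already SD(log p) ~= SD(p)/p.
    """
    p = jac.shape[1]
    jtj = jac.T @ jac
    # detect unidentifiable directions before inverting
    eigvals, eigvecs = np.linalg.eigh(jtj)
    scale = max(eigvals.max(), 1e-300)
    if eigvals.min() < 1e-12 * scale:
        null = eigvecs[:, eigvals < 1e-12 * scale]
        offenders = [
            FIT_PARAMETER_NAMES[i]
            for i in np.unique(np.argmax(np.abs(null), axis=0))
        ]
        raise UnidentifiableParameterError(
            f"singular information matrix; weakly identified: {offenders}",
            parameters=offenders,
        )
    dof = max(n_obs - p, 1)
    s2 = float(np.sum(resid**2)) / dof
    cov = s2 * np.linalg.inv(jtj)
    fsd = {name: float(np.sqrt(max(cov[i, i], 0.0)))
           for i, name in enumerate(FIT_PARAMETER_NAMES)}
    return fsd, cov


def parameter_uncertainty(fit: FitResult, dataset: CompositeDataset) -> dict[str, float]:
    """Recompute the per-parameter FSDs for a converged fit.

    FSD = sqrt(diag of weighted-least-squares covariance)/estimate,
    obtained directly on the log scale (see _fsd_from_jacobian).
    """
    fun = _residual_fn(dataset, fit.params, "observed")
    theta = _params_to_theta(fit.params)
    # central-difference Jacobian at the solution
    f0 = fun(theta)
    jac = np.empty((f0.size, theta.size))
    h = 1e-6
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        jac[:, i] = (fun(tp) - fun(tm)) / (2 * h)
    fsd, _ = _fsd_from_jacobian(jac, f0, dataset.times.size)
    return fsd
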
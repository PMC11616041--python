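"""Whole-body vitamin A kinetic model.

An 8-component linear compartmental system for retinol metabolism in
adults: compartment 1 receives the oral dose (tracer) and dietary intake
U(1); compartments 1-3 represent digestion, absorption, and chylomicron
processing (component 3 is a pure time delay of DT(3) days); chylomicron
remnant retinyl esters reach hepatocytes (compartment 4), which secrete
retinol bound to retinol-binding protein into plasma (compartment 5).
Plasma retinol exchanges with two extravascular storage pools (a larger
compartment 6 and a smaller compartment 7, together the total body
stores, TBS) or enters delay component 8, representing irreversible
tissue uptake; compartments 6 and 8 are the sites of irreversible loss.

Arrows are fractional transfer coefficients L(I,J): the fraction of
compartment J's retinol moved to compartment I per day.  Delay outputs
are written L(4,3) = L(0,8) = 1 by convention; the flux out of a delay
equals the flux that entered it one delay time earlier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import (
    DegenerateModelError,
    IntegrationError,
    ModelStructureError,
    ValidationError,
)

__all__ = [
    "RATE_KEYS",
    "FIXED_RATES",
    "ADJUSTABLE_RATES",
    "ModelParameters",
    "TracerSolution",
    "SteadyState",
    "KineticSummaries",
    "assemble_parameters",
    "load_parameters",
    "save_parameters",
    "reference_parameters",
    "simulate_tracer",
    "solve_steady_state",
    "compute_kinetic_summaries",
    "default_time_grid",
]

#: every arrow of the model, as (destination, source) pairs; 0 = out of system
RATE_KEYS: tuple[tuple[int, int], ...] = (
    (2, 1), (0, 1), (3, 2), (5, 2), (4, 3), (5, 4), (6, 5), (5, 6),
    (7, 5), (5, 7), (0, 6), (8, 5), (0, 8),
)

#: coefficients held fixed in the reference analysis (per day); the delay
#: outputs (4,3) and (0,8) are 1 by convention and never enter the dynamics
FIXED_RATES: dict[tuple[int, int], float] = {
    (2, 1): 30.0,
    (0, 1): 9.99,
    (3, 2): 30.0,
    (5, 2): 0.3,
    (4, 3): 1.0,
    (0, 8): 1.0,
}

#: the seven coefficients adjusted during fitting, excluding (8,5) which is
#: either free or eliminated by the loss-partition constraint
ADJUSTABLE_RATES: tuple[tuple[int, int], ...] = (
    (5, 4), (6, 5), (5, 6), (7, 5), (5, 7), (0, 6),
)

_KEY_NAMES = {k: f"L({k[0]},{k[1]})" for k in RATE_KEYS}


def _rate_name(key: tuple[int, int]) -> str:
    return _KEY_NAMES[key]


@dataclass(frozen=True)
class ModelParameters:
    """Fractional transfer coefficients and delay times of the model.

    Parameters
    ----------
    l : mapping (i, j) -> per-day coefficient for every arrow in RATE_KEYS
    dt3, dt8 : pure delay times of components 3 and 8, days
    constraint_mode : if True, L(8,5) is derived from the loss-partition
        rule L(8,5) = L(0,6) * L(6,5) / (L(5,6) + L(0,6)), which enforces
        R(8,5) = R(0,6) at steady state (half of the irreversible loss
        from plasma-side tissues, half from stores).
    adjustable : keys treated as adjustable during fitting ("DT(3)" for
        the delay); informational outside of model_fitting.
    """

    l: Mapping[tuple[int, int], float]
    dt3: float
    dt8: float = 0.052
    constraint_mode: bool = True
    adjustable: tuple[str, ...] = field(
        default=tuple(_KEY_NAMES[k] for k in ADJUSTABLE_RATES) + ("DT(3)",)
    )

    def __post_init__(self):
        l = dict(self.l)
        missing = [k for k in RATE_KEYS if k not in l]
        if missing:
            raise ValidationError(
                "missing coefficients: " + ", ".join(_rate_name(k) for k in missing)
            )
        for k, v in l.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{_rate_name(k)} = {v!r}: coefficients must be >= 0")
        if not (self.dt3 > 0 and self.dt8 > 0):
            raise ValidationError("delay times dt3 and dt8 must be > 0")
        if self.constraint_mode:
            l[(8, 5)] = self.constrained_l85(l)
        object.__setattr__(self, "l", l)

    @staticmethod
    def constrained_l85(l: Mapping[tuple[int, int], float]) -> float:
        """L(8,5) implied by the loss-partition rule R(8,5) = R(0,6)."""
        denom = l[(5, 6)] + l[(0, 6)]
        if l[(0, 6)] == 0.0:
            return 0.0
        if denom == 0.0:
            raise DegenerateModelError(
                "loss-partition constraint undefined: L(5,6) + L(0,6) = 0"
            )
        return l[(0, 6)] * l[(6, 5)] / denom

    @property
    def absorption_efficiency(self) -> float:
        """Fraction of an oral dose absorbed, L(2,1) / (L(2,1) + L(0,1))."""
        total = self.l[(2, 1)] + self.l[(0, 1)]
        if total == 0.0:
            raise DegenerateModelError("no exit from compartment 1")
        return self.l[(2, 1)] / total

    def to_dict(self) -> dict[str, float]:
        out = {_rate_name(k): self.l[k] for k in RATE_KEYS}
        out["DT(3)"] = self.dt3
        out["DT(8)"] = self.dt8
        return out

    def replace(self, **updates) -> "ModelParameters":
        """Return a copy with named coefficients replaced.

        Accepts field names (``dt3``) and coefficient names (``"L(6,5)"``).
        """
        l = dict(self.l)
        fields = {}
        for name, value in updates.items():
            if name.startswith("L(") or name.startswith("l("):
                i, j = name[2:-1].split(",")
                l[(int(i), int(j))] = float(value)
            else:
                fields[name] = value
        return replace(self, l=l, **fields)


def assemble_parameters(
    config: Mapping[str, float] | None = None,
    *,
    constraint_mode: bool = True,
    dt8: float | None = None,
) -> ModelParameters:
    """Build validated ModelParameters from a flat name -> value map.

    ``config`` supplies adjustable values under keys like ``"L(6,5)"`` and
    ``"DT(3)"``; coefficients absent from the map fall back to the fixed
    reference values (FIXED_RATES, DT(8) = 0.052 d).  With
    ``constraint_mode`` on, any supplied L(8,5) is ignored and recomputed
    from the loss-partition rule.
    """
    config = dict(config or {})
    l: dict[tuple[int, int], float] = dict(FIXED_RATES)
    dt3 = None
    dt8_val = 0.052 if dt8 is None else dt8
    for name, value in config.items():
        name = name.strip()
        if name.upper().startswith("L(") and name.endswith(")"):
            i, j = name[2:-1].split(",")
            l[(int(i), int(j))] = float(value)
        elif name.upper() == "DT(3)":
            dt3 = float(value)
        elif name.upper() == "DT(8)":
            dt8_val = float(value)
        # other keys (e.g. reference plasma mass) are ignored here
    if dt3 is None:
        raise ValidationError("config must supply DT(3)")
    for k in RATE_KEYS:
        if k not in l and k != (8, 5):
            raise ValidationError(f"config must supply {_rate_name(k)}")
    if (8, 5) not in l:
        if not constraint_mode:
            raise ValidationError("L(8,5) required when constraint_mode is off")
        l[(8, 5)] = 0.0  # placeholder, recomputed by the constraint
    return ModelParameters(l=l, dt3=dt3, dt8=dt8_val, constraint_mode=constraint_mode)


def load_parameters(path, *, constraint_mode: bool = True) -> ModelParameters:
    """Load a flat JSON parameter file (keys "L(2,1)" ... "DT(8)")."""
    with open(path) as fh:
        config = json.load(fh)
    return assemble_parameters(config, constraint_mode=constraint_mode)


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)


def reference_parameters(*, constraint_mode: bool = True):
    """Bundled group estimates for Ghanaian women of reproductive age.

    Returns
    -------
    (ModelParameters, m5) where ``m5`` is the group geometric-mean plasma
    retinol mass in µmol.
    """
    text = resources.files("retikin.data").joinpath("ghana_wra_reference.json").read_text()
    config = json.loads(text)
    params = assemble_parameters(config, constraint_mode=constraint_mode)
    return params, float(config["M(5)"])


# ---------------------------------------------------------------------------
# Tracer simulation
# ---------------------------------------------------------------------------

#: simulated components, in reporting order; 3 and 8 are delay elements
COMPONENTS = (1, 2, 3, 4, 5, 6, 7, 8)
LOSS_PATHS = ((0, 1), (0, 6), (0, 8))


@dataclass(frozen=True)
class TracerSolution:
    """Fraction-of-dose trajectories for every component and loss path."""

    times: np.ndarray
    fd: Mapping[int, np.ndarray]
    losses: Mapping[tuple[int, int], np.ndarray]
    dose_fraction: float
    method: str = "analytic"

    @property
    def fdp(self) -> np.ndarray:
        """Fraction of dose in plasma retinol (compartment 5)."""
        return self.fd[5]

    def total(self) -> np.ndarray:
        """Material accounted for: all compartment FDs plus cumulative losses."""
        return sum(self.fd[c] for c in COMPONENTS) + sum(
            self.losses[p] for p in LOSS_PATHS
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, component)."""
        rows = []
        for c in COMPONENTS:
            rows.append(
                pd.DataFrame(
                    {"time_d": self.times, "component": str(c), "fraction_of_dose": self.fd[c]}
                )
            )
        for p in LOSS_PATHS:
            rows.append(
                pd.DataFrame(
                    {
                        "time_d": self.times,
                        "component": f"loss({p[0]},{p[1]})",
                        "fraction_of_dose": self.losses[p],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def default_time_grid(tmax: float = 91.0, *, n_early: int = 120, n_late: int = 160) -> np.ndarray:
    """Output grid densified over 0-2 d where the tracer curve bends fastest."""
    early = np.linspace(0.0, min(2.0, tmax), n_early, endpoint=False)
    late = np.linspace(min(2.0, tmax), tmax, n_late)
    return np.unique(np.concatenate([early, late]))


def _exchange_matrix(p: ModelParameters) -> np.ndarray:
    """System matrix for the states (q4, q5, q6, q7)."""
    l = p.l
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    return np.array(
        [
            [-l[(5, 4)], 0.0, 0.0, 0.0],
            [l[(5, 4)], -k5, l[(5, 6)], l[(5, 7)]],
            [0.0, l[(6, 5)], -(l[(5, 6)] + l[(0, 6)]), 0.0],
            [0.0, l[(7, 5)], 0.0, -l[(5, 7)]],
        ]
    )


class _Resonance(Exception):
    pass


def _upstream(p: ModelParameters, dose: float):
    """Analytic solution of the feed-forward gut/chylomicron cascade.

    q1(t) = D e^{-k1 t};  q2(t) = a (e^{-k1 t} - e^{-k2 t}).
    Returns (k1, k2, a) after guarding the confluent case k1 == k2 with a
    relative nudge of 1e-9 on k2 (error far below output tolerances).
    """
    l = p.l
    k1 = l[(2, 1)] + l[(0, 1)]
    k2 = l[(3, 2)] + l[(5, 2)]
    if k1 <= 0 or k2 <= 0:
        raise DegenerateModelError("compartments 1 and 2 must both have an exit")
    if abs(k1 - k2) < 1e-9 * max(k1, k2):
        k2 = k2 * (1.0 + 1e-9)
    a = dose * l[(2, 1)] / (k2 - k1)
    return k1, k2, a


def _phi(z: np.ndarray) -> np.ndarray:
    """(e^z - 1)/z, stable for small |z| (complex-safe)."""
    z = np.asarray(z, dtype=complex)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-6
    zs = z[small]
    out[small] = 1.0 + zs / 2.0 + zs * zs / 6.0
    zl = z[~small]
    out[~small] = (np.exp(zl) - 1.0) / zl
    return out


def _simulate_analytic(p: ModelParameters, times: np.ndarray, dose: float, _depth: int = 0):
    """Exact solution of the exchange block under the analytic forcing.

    The dose transits 1 -> 2 -> delay(3) -> 4 and (via L(5,2)) directly to
    plasma; both forcing fluxes are two-exponential functions of time, so
    the response of the linear (q4, q5, q6, q7) block is a closed-form sum
    of matrix-exponential and forced-exponential modes.
    """
    l = p.l
    k1, k2, a = _upstream(p, dose)
    A = _exchange_matrix(p)
    lam, V = np.linalg.eig(A.astype(complex))
    if np.linalg.cond(V) > 1e10:
        raise _Resonance("near-defective exchange matrix")
    Vinv = np.linalg.inv(V)

    # if an upstream decay rate (nearly) coincides with an exchange
    # eigenvalue, nudge that rate by scaling its source coefficients
    # (the nudged model conserves mass exactly; the output error is O(1e-7))
    scale = max(1.0, float(np.max(np.abs(lam))))
    if _depth < 3:
        if np.min(np.abs(lam + k1)) < 1e-7 * scale:
            p2 = p.replace(**{
                "L(2,1)": l[(2, 1)] * (1 + 1e-6), "L(0,1)": l[(0, 1)] * (1 + 1e-6),
            })
            return _simulate_analytic(p2, times, dose, _depth + 1)
        if np.min(np.abs(lam + k2)) < 1e-7 * scale:
            p2 = p.replace(**{
                "L(3,2)": l[(3, 2)] * (1 + 1e-6), "L(5,2)": l[(5, 2)] * (1 + 1e-6),
            })
            return _simulate_analytic(p2, times, dose, _depth + 1)
    else:
        raise _Resonance("persistent forcing/eigenvalue resonance")

    # forcing terms: (coefficient, decay rate, onset time, target state index)
    terms = [
        (l[(5, 2)] * a, k1, 0.0, 1),
        (-l[(5, 2)] * a, k2, 0.0, 1),
        (l[(3, 2)] * a, k1, p.dt3, 0),
        (-l[(3, 2)] * a, k2, p.dt3, 0),
    ]

    def states_and_integrals(t: np.ndarray):
        """x(t) (4, nt) and X(t) = ∫_0^t x ds (4, nt)."""
        x = np.zeros((4, t.size), dtype=complex)
        X = np.zeros((4, t.size), dtype=complex)
        for c, k, tau, idx in terms:
            T = t - tau
            act = T > 0
            if not act.any():
                continue
            Ta = T[act]
            b = np.zeros(4)
            b[idx] = 1.0
            M = np.linalg.inv(A + k * np.eye(4))
            w = Vinv @ b
            eL = np.exp(np.outer(lam, Ta))  # (4, nt)
            Eb = V @ (eL * w[:, None])
            x[:, act] += c * (M @ (Eb - np.exp(-k * Ta)[None, :] * b[:, None]))
            # integral: ∫E(s)b ds = V T φ(λT) w ; ∫e^{-ks} ds = (1-e^{-kT})/k
            intE = V @ (Ta[None, :] * _phi(np.outer(lam, Ta)) * w[:, None])
            intk = -np.expm1(-k * Ta) / k
            X[:, act] += c * (M @ (intE - intk[None, :] * b[:, None]))
        return x.real, X.real

    x, X = states_and_integrals(times)
    # delay-8 bookkeeping needs the plasma integral at t - dt8
    _, X8 = states_and_integrals(np.maximum(times - p.dt8, 0.0))

    fd = _assemble_components(p, times, dose, k1, k2, a, x, X, X8)
    return fd


def _g2_cumflux(p, dose, k1, k2, a, t):
    """Cumulative flux into delay 3 through time t (analytic)."""
    l32 = p.l[(3, 2)]
    t = np.asarray(t, dtype=float)
    return l32 * a * (-np.expm1(-k1 * t) / k1 + np.expm1(-k2 * t) / k2)


def _assemble_components(p, times, dose, k1, k2, a, x, X, X8):
    l = p.l
    fd1 = dose * np.exp(-k1 * times)
    fd2 = a * (np.exp(-k1 * times) - np.exp(-k2 * times))
    g2_t = _g2_cumflux(p, dose, k1, k2, a, times)
    g2_lag = _g2_cumflux(p, dose, k1, k2, a, np.maximum(times - p.dt3, 0.0))
    fd3 = g2_t - g2_lag
    loss01 = l[(0, 1)] * dose * (-np.expm1(-k1 * times)) / k1
    loss06 = l[(0, 6)] * X[2]
    i8_t = l[(8, 5)] * X[1]
    i8_lag = l[(8, 5)] * X8[1]
    fd8 = i8_t - i8_lag
    loss08 = i8_lag
    fd = {1: fd1, 2: fd2, 3: fd3, 4: x[0], 5: x[1], 6: x[2], 7: x[3], 8: fd8}
    losses = {(0, 1): loss01, (0, 6): loss06, (0, 8): loss08}
    return fd, losses


def _simulate_ode(p: ModelParameters, times: np.ndarray, dose: float):
    """Numerical fallback: integrate the exchange block with the analytic
    upstream forcing, splitting at the delay onset DT(3)."""
    l = p.l
    k1, k2, a = _upstream(p, dose)
    A = _exchange_matrix(p)

    def q2(t):
        return a * (math.exp(-k1 * t) - math.exp(-k2 * t))

    def rhs(t, y):
        forced = np.zeros(4)
        forced[1] = l[(5, 2)] * q2(t)
        if t > p.dt3:
            forced[0] = l[(3, 2)] * q2(t - p.dt3)
        dx = A @ y[:4] + forced
        # trailing states: running integrals of plasma (q5) and compartment 6
        return np.concatenate([dx, [y[1], y[2]]])

    tmax = float(times.max()) if times.size else 0.0
    breaks = sorted({0.0, min(p.dt3, tmax), tmax})
    y0 = np.zeros(6)
    sols = []
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 <= t0:
            continue
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", rtol=1e-9, atol=1e-12,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(f"tracer integration failed on [{t0}, {t1}]: {sol.message}")
        sols.append(sol)
        y0 = sol.y[:, -1]

    def evaluate(tq):
        out = np.zeros((6, tq.size))
        for i, t in enumerate(tq):
            if t <= 0:
                continue
            for sol in sols:
                if sol.t[0] <= t <= sol.t[-1]:
                    out[:, i] = sol.sol(t)
                    break
            else:
                out[:, i] = sols[-1].sol(t)
        return out

    y = evaluate(times)
    y_lag = evaluate(np.maximum(times - p.dt8, 0.0))
    zeros = np.zeros_like(y[4])
    # only rows 1 (plasma integral) and 2 (compartment-6 integral) are used
    x, X = y[:4], np.vstack([zeros, y[4], y[5], zeros])
    X8 = np.vstack([zeros, y_lag[4], y_lag[5], zeros])
    return _assemble_components(p, times, dose, k1, k2, a, x, X, X8)


def simulate_tracer(
    params: ModelParameters,
    times: Iterable[float],
    dose_fraction: float = 1.0,
    *,
    method: str = "analytic",
) -> TracerSolution:
    """Simulate the fraction of an oral tracer dose in every component.

    A bolus of ``dose_fraction`` enters compartment 1 at t = 0; pure time
    lags of DT(3) and DT(8) days apply to the fluxes traversing the two
    delay elements.  ``method="analytic"`` evaluates the exact closed-form
    solution (the upstream cascade has no feedback, so the lagged forcing
    is analytic); ``method="ode"`` integrates numerically and is kept as a
    cross-check and as a fallback for degenerate spectra.
    """
    times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValidationError("times must be sorted and >= 0")
    if not (0 < dose_fraction <= 1):
        raise ValidationError("dose_fraction must be in (0, 1]")

    used = method
    if method == "analytic":
        try:
            fd, losses = _simulate_analytic(params, times, dose_fraction)
        except _Resonance:
            fd, losses = _simulate_ode(params, times, dose_fraction)
            used = "ode"
    elif method == "ode":
        fd, losses = _simulate_ode(params, times, dose_fraction)
    else:
        raise ValidationError(f"unknown method {method!r}")

    # numerical floor: clip tiny negative round-off
    for c in fd:
        np.clip(fd[c], 0.0, None, out=fd[c])
    for pth in losses:
        np.clip(losses[pth], 0.0, None, out=losses[pth])
    return TracerSolution(times=times, fd=fd, losses=losses,
                          dose_fraction=dose_fraction, method=used)


# ---------------------------------------------------------------------------
# Steady state and derived summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyState:
    """Tracee masses and transfer rates at vitamin A balance.

    ``m`` holds compartment masses (µmol) including delay contents (the
    mass in a delay equals flux x delay time); ``r`` holds transfer rates
    R(I,J) = L(I,J) x M(J) in µmol/d, with the delay throughputs recorded
    as R(4,3) and R(0,8) equal to the flux traversing each delay.
    """

    m: Mapping[int, float]
    r: Mapping[tuple[int, int], float]
    tbs: float
    dr: float
    u1: float
    absorption_efficiency: float

    def to_dict(self) -> dict[str, float]:
        out = {f"M({c})": self.m[c] for c in sorted(self.m)}
        out.update({f"R({i},{j})": v for (i, j), v in self.r.items()})
        out.update(
            TBS=self.tbs, DR=self.dr, **{"U(1)": self.u1},
            absorption_efficiency=self.absorption_efficiency,
        )
        return out


def solve_steady_state(params: ModelParameters, m5: float) -> SteadyState:
    """Solve the tracee mass balance given the plasma retinol mass M(5).

    Unknowns are the masses of compartments 1, 2, 4, 6, 7 and the dietary
    input U(1); each compartment's inflow is equated to its outflow.  The
    disposal rate DR = R(0,6) + R(8,5) (all flux through delay 8 exits),
    and U(1) x absorption efficiency = DR by whole-system balance.
    """
    if not m5 > 0:
        raise ValidationError("m5 must be > 0")
    l = params.l
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    # unknown order: m1, m2, m4, m6, m7, u1
    A = np.array(
        [
            [-(l[(2, 1)] + l[(0, 1)]), 0, 0, 0, 0, 1],       # compartment 1
            [l[(2, 1)], -(l[(3, 2)] + l[(5, 2)]), 0, 0, 0, 0],  # compartment 2
            [0, l[(3, 2)], -l[(5, 4)], 0, 0, 0],              # compartment 4
            [0, l[(5, 2)], l[(5, 4)], l[(5, 6)], l[(5, 7)], 0],  # compartment 5
            [0, 0, 0, -(l[(5, 6)] + l[(0, 6)]), 0, 0],        # compartment 6
            [0, 0, 0, 0, -l[(5, 7)], 0],                      # compartment 7
        ],
        dtype=float,
    )
    b = np.array([0, 0, 0, k5 * m5, -l[(6, 5)] * m5, -l[(7, 5)] * m5], dtype=float)
    try:
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned balance system")
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError(f"singular steady-state balance system: {exc}") from exc
    m1, m2, m4, m6, m7, u1 = x
    if min(m1, m2, m4, m6, m7, u1) < 0:
        raise DegenerateModelError("steady state has a negative mass or input")

    flux3 = l[(3, 2)] * m2
    flux8 = l[(8, 5)] * m5
    m = {
        1: m1, 2: m2, 3: flux3 * params.dt3, 4: m4, 5: m5,
        6: m6, 7: m7, 8: flux8 * params.dt8,
    }
    masses = {1: m1, 2: m2, 4: m4, 5: m5, 6: m6, 7: m7}
    r = {k: l[k] * masses[k[1]] for k in RATE_KEYS if k[1] in masses}
    r[(4, 3)] = flux3   # delay throughput
    r[(0, 8)] = flux8
    tbs = m6 + m7
    dr = r[(0, 6)] + r[(8, 5)]
    return SteadyState(
        m=m, r=r, tbs=tbs, dr=dr, u1=u1,
        absorption_efficiency=params.absorption_efficiency,
    )


@dataclass(frozen=True)
class KineticSummaries:
    """Derived descriptors of plasma retinol turnover."""

    transit_time_plasma_h: float
    residence_time_plasma_d: float
    recycling_number: float
    time_to_recycle_d: float
    fcr_percent_per_day: float
    store_half_life_d: float
    years_of_stores: float
    plasma_visits: float

    def to_dict(self) -> dict[str, float]:
        return {
            "transit_time_plasma_h": self.transit_time_plasma_h,
            "residence_time_plasma_d": self.residence_time_plasma_d,
            "recycling_number": self.recycling_number,
            "time_to_recycle_d": self.time_to_recycle_d,
            "fcr_percent_per_day": self.fcr_percent_per_day,
            "store_half_life_d": self.store_half_life_d,
            "years_of_stores": self.years_of_stores,
            "plasma_visits": self.plasma_visits,
        }


def plasma_return_probability(params: ModelParameters) -> float:
    """Probability that a retinol molecule leaving plasma returns to it.

    From the embedded jump chain: an exit goes to compartment 6, 7, or
    delay 8 in proportion to the rate constants; from 6 it returns with
    probability L(5,6)/(L(5,6)+L(0,6)), from 7 with probability 1, from
    delay 8 never.
    """
    l = params.l
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    if k5 <= 0:
        raise ModelStructureError("no exit from plasma")
    p6 = l[(6, 5)] / k5
    p7 = l[(7, 5)] / k5
    ret6 = l[(5, 6)] / (l[(5, 6)] + l[(0, 6)]) if (l[(5, 6)] + l[(0, 6)]) > 0 else 0.0
    return p6 * ret6 + p7


def compute_kinetic_summaries(
    params: ModelParameters,
    ss: SteadyState,
    *,
    half_life_rule: str = "fifty",
) -> KineticSummaries:
    """Transit/residence times, recycling, FCR and store longevity.

    Residence time is the expected number of plasma visits (an
    absorbing-Markov-chain quantity, 1/(1 - return probability)) times the
    single-pass transit time.  The recycling number is reported as
    expected visits minus one.  The store half-life uses the convention
    t1/2 = 50% / FCR%/d by default; ``half_life_rule="ln2"`` gives the
    exponential ln(2)/FCR variant.
    """
    l = params.l
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    if k5 <= 0:
        raise ModelStructureError("no exit from plasma compartment")
    transit_d = 1.0 / k5
    p_return = plasma_return_probability(params)
    if p_return >= 1.0:
        raise ModelStructureError(
            f"plasma return probability {p_return} >= 1: no irreversible exit"
        )
    visits = 1.0 / (1.0 - p_return)
    residence_d = visits * transit_d

    # flux-weighted mean of storage-compartment transit times
    w6 = l[(6, 5)] / (l[(6, 5)] + l[(7, 5)])
    t6 = 1.0 / (l[(5, 6)] + l[(0, 6)])
    t7 = 1.0 / l[(5, 7)]
    time_to_recycle = w6 * t6 + (1.0 - w6) * t7

    traced_pool = ss.m[5] + ss.m[6] + ss.m[7]
    fcr = 100.0 * ss.dr / traced_pool
    if half_life_rule == "fifty":
        half_life = 50.0 / fcr
    elif half_life_rule == "ln2":
        half_life = 100.0 * math.log(2.0) / fcr
    else:
        raise ValidationError(f"unknown half_life_rule {half_life_rule!r}")
    years = ss.tbs / ss.dr / 365.0

    return KineticSummaries(
        transit_time_plasma_h=24.0 * transit_d,
        residence_time_plasma_d=residence_d,
        recycling_number=visits - 1.0,
        time_to_recycle_d=time_to_recycle,
        fcr_percent_per_day=fcr,
        store_half_life_d=half_life,
        years_of_stores=years,
        plasma_visits=visits,
    )
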
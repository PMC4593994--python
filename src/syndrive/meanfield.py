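"""Two-class mean excitatory / mean inhibitory synaptic-drive model.

Collapsing the network to population averages (ignoring deviations of the
weights and drives from their block means) gives the planar system

    dSE/dt = f(a*SE - b*SI + vthE) - SE / lamE,
    dSI/dt = f(c*SE - d*SI + vthI) - SI / lamI,

where ``a = nE*mean(AEE)``, ``b = -nI*mean(AEI)``, ``c = nE*mean(AIE)``,
``d = -nI*mean(AII)`` are nonnegative aggregate gains and ``f`` is the
logistic activation with ceiling ``f_max`` and slope ``gamma``.

This module provides the vector field, trajectory integration (first- and
second-order kernels), nullclines and their inverses, equilibrium location
with Jacobian trace/determinant classification, the closed-form conditions
for a unique equilibrium with positive determinant, Hopf-candidate scanning
(trace-zero crossings of the unique equilibrium), limit-cycle detection, and
the Hill dose-response utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable
import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.special import expit

from .simulate import Trajectory, _solve
from .network import NeuronalNetwork  # noqa: F401  (re-exported context)

_EPS_FRAC = 1e-9  # equilibrium search keeps away from the box edge, where f^-1 diverges


@dataclass(frozen=True)
class MeanFieldParams:
    """Aggregate parameters of the two-class mean-field model.

    ``a``-``d`` are the nonnegative coupling aggregates (see module
    docstring), ``vthE``/``vthI`` the threshold inputs (volts), ``lamE``/
    ``lamI`` the population time constants (s), and ``f_max``/``gamma`` the
    logistic activation parameters.
    """

    a: float
    b: float
    c: float
    d: float
    vthE: float
    vthI: float
    lamE: float = 1.0
    lamI: float = 1.0
    f_max: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("lamE", "lamI", "f_max", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def f(self, x):
        return self.f_max * expit(self.gamma * np.asarray(x, dtype=float))

    def fprime(self, x):
        fx = self.f(x)
        return self.gamma * fx * (1.0 - fx / self.f_max)

    @property
    def box(self) -> tuple[float, float]:
        """Upper corner of the positively invariant box [0,box[0]]x[0,box[1]]."""
        return (self.f_max * self.lamE, self.f_max * self.lamI)


@dataclass
class EquilibriumReport:
    """An equilibrium with its Jacobian-based classification."""

    point: tuple[float, float]
    jacobian: np.ndarray
    trace: float
    det: float
    eigenvalues: np.ndarray
    classification: str  # stable | unstable | marginal


@dataclass
class BifurcationScan:
    """Result of a one-parameter trace-zero (Hopf-candidate) scan."""

    param_name: str
    grid: np.ndarray
    traces: np.ndarray
    dets: np.ndarray
    classifications: list[str]
    crossings: list[float]
    equilibria: np.ndarray  # (n_grid, 2) equilibrium coordinates
    extrema: tuple[float, float] | None = None  # (SE_max, SE_min) of the E nullcline


def meanfield_rhs(p: MeanFieldParams, state) -> np.ndarray:
    """Vector field of the two-class model at ``state = (SE, SI)``."""
    SE, SI = np.asarray(state, dtype=float)
    return np.array([
        p.f(p.a * SE - p.b * SI + p.vthE) - SE / p.lamE,
        p.f(p.c * SE - p.d * SI + p.vthI) - SI / p.lamI,
    ])


def simulate_meanfield(p: MeanFieldParams, S0, t_span, *, rtol: float = 1e-8,
                       atol: float = 1e-10, method: str = "RK45",
                       n_points: int = 4001, t_eval=None) -> Trajectory:
    """Integrate the planar mean-field model.

    Starting points outside the invariant box produce a warning, not an
    error; trajectories started inside the box remain inside it.
    """
    S0 = np.asarray(S0, dtype=float)
    bx = p.box
    if not (0 <= S0[0] <= bx[0] and 0 <= S0[1] <= bx[1]):
        warnings.warn("initial state lies outside the invariant box "
                      f"[0,{bx[0]}]x[0,{bx[1]}]", stacklevel=2)

    def rhs(t, y):
        return meanfield_rhs(p, y)

    sol = _solve(None, rhs, S0, t_span, rtol=rtol, atol=atol, max_step=np.inf,
                 method=method, n_points=n_points, t_eval=t_eval)
    return Trajectory(times=sol.t, S=sol.y.T, labels=["SE_bar", "SI_bar"],
                      meta={"model": "meanfield", "rtol": rtol, "atol": atol})


def simulate_meanfield_second_order(p: MeanFieldParams, S0, Sdot0, t_span, *,
                                    rtol: float = 1e-8, atol: float = 1e-10,
                                    method: str = "RK45", n_points: int = 4001,
                                    t_eval=None) -> Trajectory:
    """Integrate the second-order (Erlang-kernel) mean-field model.

    The aggregates enter exactly as in the first-order model; each population
    mean obeys a damped second-order equation forced by the shared firing
    rate.
    """
    S0 = np.asarray(S0, dtype=float)
    Sdot0 = np.asarray(Sdot0, dtype=float)
    lam = np.array([p.lamE, p.lamI])

    def rhs(t, y):
        S, Sd = y[:2], y[2:]
        force = np.array([
            p.f(p.a * S[0] - p.b * S[1] + p.vthE),
            p.f(p.c * S[0] - p.d * S[1] + p.vthI),
        ])
        return np.concatenate([Sd, -2.0 / lam * Sd - S / lam**2 + force])

    sol = _solve(None, rhs, np.concatenate([S0, Sdot0]), t_span, rtol=rtol,
                 atol=atol, max_step=np.inf, method=method, n_points=n_points,
                 t_eval=t_eval)
    return Trajectory(times=sol.t, S=sol.y[:2].T, Sdot=sol.y[2:].T,
                      labels=["SE_bar", "SI_bar"],
                      meta={"model": "meanfield2", "rtol": rtol, "atol": atol})


@dataclass
class Nullclines:
    """Nullcline functions of the mean-field model.

    ``g(SE)`` gives the inhibitory drive on the dSE/dt = 0 curve; ``h(SI)``
    gives the excitatory drive on the dSI/dt = 0 curve; ``finv`` is the
    logistic inverse (defined on the open interval ``(0, f_max*lam)`` after
    scaling); ``h`` is strictly increasing so ``hinv`` exists and is
    evaluated by bisection.
    """

    p: MeanFieldParams

    def finv(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0) or np.any(x >= self.p.f_max):
            raise ValueError("finv argument must lie strictly inside (0, f_max)")
        return np.log(x / (self.p.f_max - x)) / self.p.gamma

    def g(self, SE):
        p = self.p
        return (p.a * SE + p.vthE - self.finv(np.asarray(SE) / p.lamE)) / p.b

    def h(self, SI):
        p = self.p
        return (p.d * SI - p.vthI + self.finv(np.asarray(SI) / p.lamI)) / p.c

    def gprime(self, SE):
        p = self.p
        SE = np.asarray(SE, dtype=float)
        return (p.a - p.f_max * p.lamE
                / (p.gamma * SE * (p.f_max * p.lamE - SE))) / p.b

    def hprime(self, SI):
        p = self.p
        SI = np.asarray(SI, dtype=float)
        return (p.d + p.f_max * p.lamI
                / (p.gamma * SI * (p.f_max * p.lamI - SI))) / p.c

    def hinv(self, x: float, tol: float = 1e-12) -> float:
        """Invert the increasing ``h`` by bisection on (0, f_max*lamI)."""
        p = self.p
        eps = _EPS_FRAC * p.f_max * p.lamI
        lo, hi = eps, p.f_max * p.lamI - eps
        if self.h(lo) > x or self.h(hi) < x:
            raise ValueError("hinv argument outside the attainable range")
        return float(brentq(lambda s: self.h(s) - x, lo, hi, xtol=tol))


def nullclines(p: MeanFieldParams) -> Nullclines:
    """Nullcline curves, slopes, and inverses for the mean-field model."""
    return Nullclines(p)


def _jacobian_at(p: MeanFieldParams, SE: float, SI: float) -> np.ndarray:
    # closed-form Jacobian using f' = gamma f (1 - f/f_max) at the equilibrium,
    # where f(...) = SE/lamE and f(...) = SI/lamI respectively
    kE = p.gamma * SE / p.lamE * (1.0 - SE / (p.f_max * p.lamE))
    kI = p.gamma * SI / p.lamI * (1.0 - SI / (p.f_max * p.lamI))
    return np.array([[-1.0 / p.lamE + p.a * kE, -p.b * kE],
                     [p.c * kI, -1.0 / p.lamI - p.d * kI]])


def _classify(tr: float, det: float, tol: float = 1e-8) -> str:
    if det > 0 and abs(tr) <= tol:
        return "marginal"
    if det > 0 and tr < 0:
        return "stable"
    return "unstable"


def find_equilibria(p: MeanFieldParams, n_samples: int = 2000) -> list[EquilibriumReport]:
    """Locate all equilibria by dense sampling plus root polishing.

    The equilibrium condition is reduced to a scalar residual in ``SE`` on
    the open interval ``(0, f_max*lamE)`` (the logistic is positive, so
    boundary equilibria cannot occur); each sign-change bracket is polished
    with Brent's method and the Jacobian evaluated in closed form.  Roots
    closer together than the sampling resolution would be missed; the
    default 2000 samples resolve the models treated here comfortably.
    """
    nc = Nullclines(p)
    eps = _EPS_FRAC * p.f_max * p.lamE
    SE = np.linspace(eps, p.f_max * p.lamE - eps, n_samples)

    def resid(se):
        si = nc.g(se)
        return p.f(p.c * se - p.d * si + p.vthI) - si / p.lamI

    r = resid(SE)
    out: list[EquilibriumReport] = []
    for i in np.nonzero(np.diff(np.sign(r)) != 0)[0]:
        se = float(brentq(resid, SE[i], SE[i + 1], xtol=1e-15, rtol=8.9e-16))
        si = float(nc.g(se))
        J = _jacobian_at(p, se, si)
        tr, det = float(np.trace(J)), float(np.linalg.det(J))
        out.append(EquilibriumReport(point=(se, si), jacobian=J, trace=tr,
                                     det=det, eigenvalues=np.linalg.eigvals(J),
                                     classification=_classify(tr, det)))
    return out


def prop3_conditions(p: MeanFieldParams) -> dict:
    """Closed-form conditions for a unique equilibrium with det J > 0.

    ``cond_a`` requires the excitatory self-coupling to exceed
    ``4/(gamma*f_max*lamE)`` so the E nullcline is S-shaped with interior
    extrema; ``cond_slope`` compares the maximal slopes of the two
    nullclines; ``cond_gap`` compares the vertical extents between the
    nullcline extrema (evaluated numerically through the bisection inverse
    of ``h``).  When all three hold, threshold inputs exist for which the
    system has exactly one equilibrium and its Jacobian determinant is
    positive.
    """
    g_, fm, lE, lI = p.gamma, p.f_max, p.lamE, p.lamI
    cond_a = p.a > 4.0 / (g_ * fm * lE)
    out: dict = {"cond_a": bool(cond_a), "cond_slope": None, "cond_gap": None,
                 "extrema": None}
    if not cond_a:
        return out
    disc = np.sqrt((fm * lE) ** 2 - 4.0 * fm * lE / (p.a * g_))
    SE_max = (fm * lE + disc) / 2.0
    SE_min = (fm * lE - disc) / 2.0
    out["extrema"] = (float(SE_max), float(SE_min))
    out["cond_slope"] = bool(
        4.0 / (p.c * g_ * fm * lI)
        < p.b * g_ * fm * lE / (p.a * g_ * fm * lE - 4.0) - p.d / p.c)
    nc = Nullclines(p)
    rhs = (p.a * disc - (2.0 / g_) * np.log(
        p.a * g_ * (fm * lE + disc) ** 2 / (4.0 * fm * lE))) / p.b
    out["cond_gap"] = bool(nc.hinv(SE_max) - nc.hinv(SE_min) > rhs)
    return out


_SCANNABLE = ("vthE", "vthI", "lamE", "lamI", "a", "b", "c", "d")


def hopf_scan(p: MeanFieldParams, param_name: str, lo: float, hi: float,
              tol: float = 1e-3, n_grid: int = 200) -> BifurcationScan:
    """Scan one parameter for trace-zero crossings of the unique equilibrium.

    At each grid value the unique equilibrium is located and its Jacobian
    trace and determinant recorded; each sign change of the trace is then
    polished by Brent's method (well below the requested ``tol``), and
    reported as a Hopf candidate when the determinant is positive there, so
    the eigenvalues form a purely imaginary pair at the crossing.  A grid
    value with zero or multiple equilibria raises an error naming the value.
    """
    if param_name not in _SCANNABLE:
        raise ValueError(f"cannot scan {param_name!r}; choose one of {_SCANNABLE}")

    def at(v: float) -> EquilibriumReport:
        eqs = find_equilibria(replace(p, **{param_name: float(v)}))
        if len(eqs) != 1:
            raise ValueError(f"expected exactly one equilibrium at {param_name}={v:.6g}, "
                             f"found {len(eqs)}")
        return eqs[0]

    grid = np.linspace(lo, hi, n_grid)
    reports = [at(v) for v in grid]
    traces = np.array([r.trace for r in reports])
    dets = np.array([r.det for r in reports])
    eq_pts = np.array([r.point for r in reports])
    classifications = [r.classification for r in reports]

    crossings: list[float] = []
    for i in np.nonzero(np.diff(np.sign(traces)) != 0)[0]:
        root = float(brentq(lambda v: at(v).trace, grid[i], grid[i + 1],
                            xtol=min(tol, 1e-10)))
        if at(root).det > 0:
            crossings.append(root)

    p3 = prop3_conditions(p)
    return BifurcationScan(param_name=param_name, grid=grid, traces=traces,
                           dets=dets, classifications=classifications,
                           crossings=crossings, equilibria=eq_pts,
                           extrema=p3["extrema"])


def detect_limit_cycle(traj: Trajectory, transient_fraction: float = 0.5,
                       zero_tol: float = 1e-3) -> dict:
    """Decide whether the tail of a planar trajectory is a sustained cycle.

    The transient is discarded; a limit cycle is reported when the tail
    peak-to-peak amplitude of the first state exceeds ``10*zero_tol`` and
    at least three local maxima occur at equispaced times (within 2%).
    Peaks must be prominent at the 1% level of the tail amplitude.
    """
    if traj.n_states != 2:
        raise ValueError("limit-cycle detection expects a planar (2-state) trajectory")
    k0 = int(transient_fraction * traj.times.size)
    s, t = traj.S[k0:, 0], traj.times[k0:]
    amp = float(np.ptp(s))
    result = {"exists": False, "amplitude": amp, "period": None,
              "insufficient_data": False}
    if amp <= 10.0 * zero_tol:
        return result
    peaks, _ = find_peaks(s, prominence=0.01 * amp)
    if peaks.size < 3:
        result["insufficient_data"] = True
        return result
    intervals = np.diff(t[peaks])
    period = float(np.mean(intervals))
    if np.max(np.abs(intervals - period)) <= 0.02 * period:
        result["exists"] = True
        result["period"] = period
    return result


def hill_probability(C, C50: float, gamma_h: float):
    """Hill dose-response: probability of drug effect at concentration ``C``.

    ``P = C**g / (C50**g + C**g)``, evaluated in the log domain for
    stability at the steep exponents (6-20) typical of anesthetic
    concentration-response curves.  ``P(C50) = 1/2`` exactly.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be nonnegative")
    if not C50 > 0:
        raise ValueError("C50 must be positive")
    if not gamma_h > 0:
        raise ValueError("the Hill exponent must be positive")
    with np.errstate(divide="ignore"):
        out = expit(gamma_h * (np.log(C) - np.log(C50)))
    return out if out.ndim else float(out)
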
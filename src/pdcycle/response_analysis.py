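"""Dose-response sweeps and derived metrics: Hill numbers and bell shapes.

A dose-response here is the steady-state phosphorylated fraction R as a
function of one total concentration (usually the kinase pool Kt, sometimes
the substrate pool St), computed by the exact analytic solution (basic
cycle), full-ODE relaxation (any variant) or the tQSSA reduction
(phosphatase-active complex).  On top of the curve the module computes

* numeric response-coefficient Hill numbers relative to the curve's own
  plateau,
* bell-shape metrics: Rmax/R_inf for Kt sweeps and Rmax/R0 for St sweeps,
  where a ratio above 1 diagnoses a non-monotonic (bell-shaped) response,
* 1-D/2-D parameter scans of these metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import basic_analytic, kinetics, tqssa
from .model_core import ModelVariant, Pools, RateParams, derive_constants

__all__ = [
    "DoseResponse",
    "ScanResult",
    "dose_response",
    "r_inf_extended_Pactive",
    "hill_number_numeric",
    "bell_metrics_kt",
    "bell_metrics_st",
    "scan_2d",
    "default_grid",
]

BELL_THRESHOLD = 1.05  # ratio above which a response counts as bell-shaped


@dataclass
class DoseResponse:
    control: str  # "Kt" | "Pt" | "St"
    grid: np.ndarray
    R: np.ndarray
    method: str  # "analytic" | "ode" | "tqssa"
    params: RateParams
    pools: Pools
    variant: ModelVariant
    R_inf: float | None = None
    metrics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "control_name": self.control,
            "control_uM": self.grid,
            "R": self.R,
            "method": self.method,
        })


@dataclass
class ScanResult:
    axis1: str
    axis2: str
    grid1: np.ndarray
    grid2: np.ndarray
    metric: str
    values: np.ndarray  # shape (len(grid1), len(grid2))
    threshold: float | None = None

    @property
    def mask(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no threshold set for this scan")
        with np.errstate(invalid="ignore"):
            return self.values > self.threshold

    def to_frame(self) -> pd.DataFrame:
        g1, g2 = np.meshgrid(self.grid1, self.grid2, indexing="ij")
        df = pd.DataFrame({
            self.axis1: g1.ravel(),
            self.axis2: g2.ravel(),
            self.metric: self.values.ravel(),
        })
        if self.threshold is not None:
            df["above_threshold"] = self.mask.ravel()
        return df


def default_grid(lo: float = 1e-2, hi: float = 1e3, per_decade: int = 40) -> np.ndarray:
    n = max(int(np.log10(hi / lo) * per_decade), 2)
    return np.logspace(np.log10(lo), np.log10(hi), n)


def dose_response(
    params: RateParams,
    pools: Pools,
    variant: ModelVariant,
    control: str = "Kt",
    grid=None,
    method: str = "analytic",
) -> DoseResponse:
    """Steady-state R along a log-spaced sweep of one total concentration.

    The ODE backend continues each steady state from the previous grid
    point's solution (falling back to the unphosphorylated start), so sweeps
    follow one branch; failed grid points are NaN-flagged, not fatal.
    """
    variant = ModelVariant(variant)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("grid must be non-negative and strictly increasing")
    if control not in ("Kt", "Pt", "St"):
        raise ValueError(f"unknown control variable {control!r}")

    R = np.full(grid.shape, np.nan)
    if method == "analytic":
        if variant is not ModelVariant.BASIC:
            raise ValueError("analytic backend is exact only for the basic cycle")
        for i, x in enumerate(grid):
            p = pools.replace(**{control: x})
            try:
                R[i] = basic_analytic.r_from_sk(
                    basic_analytic.solve_sk(params, p), params, p
                )
            except basic_analytic.DomainError:
                pass
    elif method == "ode":
        y_prev = None
        for i, x in enumerate(grid):
            p = pools.replace(**{control: x})
            try:
                y0 = _carry_state(y_prev, p, variant) if y_prev is not None else None
                ss = kinetics.steady_state_numeric(params, p, variant, y0=y0)
                R[i] = ss.R
                y_prev = ss.state
            except kinetics.SteadyStateError:
                y_prev = None
    elif method == "tqssa":
        if control != "Kt":
            raise ValueError("tqssa backend sweeps Kt only")
        R, _, _ = tqssa.tqssa_steady_state(params, pools, grid, variant=variant)
    else:
        raise ValueError(f"unknown method {method!r}")

    dr = DoseResponse(control, grid, R, method, params, pools, variant)
    if control == "Kt" and variant is ModelVariant.BASIC:
        dr.R_inf = basic_analytic.sk_inf_kt(params, pools).R_inf
    elif control == "Kt" and variant is ModelVariant.COMPLEX_P_ACTIVE and params.k3 > 0:
        dr.R_inf = r_inf_extended_Pactive(params, pools)
    return dr


def _carry_state(y_prev, pools: Pools, variant: ModelVariant):
    """Adapt the previous steady state to the new pool totals (continuation)."""
    y = np.array(y_prev, dtype=float)
    if variant is ModelVariant.BASIC:
        # (S,Sp,SpP,SK): rebalance substrate into S, cap complexes by pools
        y[3] = min(y[3], pools.Kt)
        y[2] = min(y[2], pools.Pt)
        y[0] = max(pools.St - y[1] - y[2] - y[3], 0.0)
        return y
    bound_p = y[2] + y[6] + y[7] + y[8]
    bound_k = y[3] + y[6] + y[7] + y[8]
    if bound_p > pools.Pt or bound_k > pools.Kt:
        return None  # shrinking pools: restart from the default state
    y[4] = pools.Pt - bound_p
    y[5] = pools.Kt - bound_k
    y[0] = max(pools.St - y[1] - y[2] - y[3] - y[7] - y[8], 0.0)
    return y


def r_inf_extended_Pactive(params: RateParams, pools: Pools) -> float:
    """Large-Kt plateau of the phosphatase-active extended model.

    At saturating kinase essentially all phosphatase is complexed, so the
    system reduces to a basic cycle whose phosphatase arm is the complex arm:
    substitute (lambda3, lambda_m3, k3) for (lambda1, lambda_m1, k1) in the
    basic-model asymptote.
    """
    if params.k3 <= 0 or params.lambda3 <= 0:
        raise ValueError("phosphatase-active complex requires lambda3, k3 > 0")
    sub = params.replace(
        lambda1=params.lambda3, lambda_m1=params.lambda_m3, k1=params.k3,
        lambda3=0.0, lambda_m3=0.0, k3=0.0, kappa1=0.0, kappa_m1=0.0,
    )
    return basic_analytic.sk_inf_kt(sub, pools).R_inf


def hill_number_numeric(curve: DoseResponse, R_inf: float | None = None) -> float:
    """Response-coefficient Hill number of a numeric dose-response curve.

    The plateau defaults to the curve's attached R_inf, else the mean of the
    last two grid points.  Only the monotone rising segment up to the curve
    maximum is used; curves that never reach 90% of the plateau on the grid
    raise with a request to extend it.
    """
    ok = ~np.isnan(curve.R)
    x, r = curve.grid[ok], curve.R[ok]
    if R_inf is None:
        R_inf = curve.R_inf if curve.R_inf is not None else float(np.mean(r[-2:]))
    imax = int(np.argmax(r))
    xs, rs = x[: imax + 1], r[: imax + 1]
    if np.any(np.diff(rs) < -1e-9):
        raise ValueError(
            "curve is non-monotone before its maximum; use bell metrics instead"
        )
    lo, hi = 0.1 * R_inf, 0.9 * R_inf
    if rs[-1] < hi or rs[0] > lo:
        raise ValueError(
            "grid does not bracket the 10%/90% plateau crossings; extend it"
        )
    k10 = float(np.exp(np.interp(lo, rs, np.log(xs))))
    k90 = float(np.exp(np.interp(hi, rs, np.log(xs))))
    return float(np.log(81.0) / np.log(k90 / k10))


def _parabolic_peak(logx, y, i):
    """Three-point parabolic refinement of a discrete maximum in log-x."""
    if i == 0 or i == len(y) - 1:
        return logx[i], y[i], True  # boundary: flagged
    x0, x1, x2 = logx[i - 1], logx[i], logx[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:
        return x1, y1, False
    dx = 0.5 * (y0 - y2) / denom * (x2 - x0) / 2
    ypk = y1 - 0.25 * (y0 - y2) * dx / ((x2 - x0) / 2)
    return x1 + dx, float(ypk), False


def bell_metrics_kt(curve: DoseResponse, R_inf: float | None = None) -> dict:
    """Peak metrics of a Kt sweep: Rmax, Rmax/R_inf and the peak position.

    A ratio Rmax/R_inf > 1 diagnoses the bell shape: the response overshoots
    its own saturating-kinase plateau.  A peak on the grid boundary is
    flagged rather than silently refined.
    """
    if R_inf is None:
        R_inf = curve.R_inf
    if R_inf is None:
        raise ValueError("R_inf required (attach to curve or pass explicitly)")
    ok = ~np.isnan(curve.R)
    x, r = curve.grid[ok], curve.R[ok]
    i = int(np.argmax(r))
    logxpk, rpk, boundary = _parabolic_peak(np.log(x), r, i)
    rpk = max(rpk, r[i])
    return {
        "Rmax": float(rpk),
        "ratio": float(rpk / R_inf),
        "argmax_Kt": float(np.exp(logxpk)),
        "R_inf": float(R_inf),
        "boundary_peak": bool(boundary),
        "bell": bool(rpk / R_inf > BELL_THRESHOLD and not boundary),
    }


def bell_metrics_st(curve: DoseResponse, R0: float | None = None) -> dict:
    """Peak metrics of an St sweep: RmaxSt, RmaxSt/R0 and classification.

    R0 is the small-St limit of R; by default it is computed analytically at
    St = 1e-6 * min(Pt, M1) (validated stable under halving in the tests).
    """
    if curve.control != "St":
        raise ValueError("bell_metrics_st expects an St sweep")
    if R0 is None:
        dc = derive_constants(curve.params)
        st0 = 1e-6 * min(curve.pools.Pt, dc.M1)
        p0 = curve.pools.replace(St=st0)
        R0 = basic_analytic.r_from_sk(
            basic_analytic.solve_sk(curve.params, p0), curve.params, p0
        )
    ok = ~np.isnan(curve.R)
    x, r = curve.grid[ok], curve.R[ok]
    i = int(np.argmax(r))
    logxpk, rpk, boundary = _parabolic_peak(np.log(x), r, i)
    rpk = max(rpk, r[i])
    return {
        "RmaxSt": float(rpk),
        "R0": float(R0),
        "ratio": float(rpk / R0),
        "argmax_St": float(np.exp(logxpk)),
        "boundary_peak": bool(boundary),
        "bell": bool(rpk / R0 > BELL_THRESHOLD and not boundary),
    }


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------

# Derived-axis specs: name -> (free rate that realizes the axis, setter)
_AXIS_SETTERS: dict[str, Callable[[RateParams, Pools, float], tuple[RateParams, Pools]]] = {
    "omega": lambda p, q, v: (p.replace(kappa_m1=v * p.kappa1), q),
    "M3": lambda p, q, v: (p.replace(lambda3=(p.lambda_m3 + p.k3) / v), q),
    "M1": lambda p, q, v: (p.replace(lambda1=(p.lambda_m1 + p.k1) / v), q),
    "alpha": lambda p, q, v: (p.replace(k2=v * p.k1), q),
    "lambda1_over_lambda2": lambda p, q, v: (p.replace(lambda1=v * p.lambda2), q),
    "St_over_Pt": lambda p, q, v: (p, q.replace(St=v * q.Pt)),
    "Pt_over_Kt": lambda p, q, v: (p, q.replace(Pt=v * q.Kt)),
    "Pt": lambda p, q, v: (p, q.replace(Pt=v)),
    "St": lambda p, q, v: (p, q.replace(St=v)),
    "Kt": lambda p, q, v: (p, q.replace(Kt=v)),
}


def _metric_fns(variant, kt_grid, st_grid):
    def r_inf(params, pools):
        return basic_analytic.sk_inf_kt(params, pools).R_inf

    def nH(params, pools):
        return basic_analytic.hill_number_analytic(params, pools).nH

    def rmax_st_over_r0(params, pools):
        # a monotone curve has its maximum on the sweep boundary, not a bell
        # peak; report 1 there so threshold masks isolate true bells
        grid = st_grid if st_grid is not None else default_grid(1e-2, 1e6, 15)
        curve = dose_response(params, pools, ModelVariant.BASIC, "St", grid, "analytic")
        m = bell_metrics_st(curve)
        return m["ratio"] if not m["boundary_peak"] else 1.0

    def rmax_kt_over_r_inf(params, pools):
        grid = kt_grid if kt_grid is not None else default_grid(1e-2, 1e3, 10)
        curve = dose_response(params, pools, variant, "Kt", grid, "tqssa")
        return bell_metrics_kt(curve, r_inf_extended_Pactive(params, pools))["ratio"]

    return {
        "R_inf": r_inf,
        "nH": nH,
        "RmaxSt_over_R0": rmax_st_over_r0,
        "RmaxKt_over_R_inf": rmax_kt_over_r_inf,
    }


def scan_2d(
    params: RateParams,
    pools: Pools,
    variant: ModelVariant,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    metric: str,
    threshold: float | None = None,
    kt_grid=None,
    st_grid=None,
) -> ScanResult:
    """Evaluate a response metric on a 2-D grid of derived parameter axes.

    Each axis names either a pool, a raw rate ratio, or a derived constant
    with its designated free variable (omega varies kappa_m1; M3 varies
    lambda3; lambda1/lambda2 varies lambda1), matching the printed scans.
    Points where the metric cannot be evaluated are NaN.
    """
    variant = ModelVariant(variant)
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _AXIS_SETTERS:
            raise ValueError(
                f"axis {name!r} has no designated free variable; known: "
                f"{sorted(_AXIS_SETTERS)}"
            )
    fns = _metric_fns(variant, kt_grid, st_grid)
    if metric not in fns:
        raise ValueError(f"unknown metric {metric!r}; known: {sorted(fns)}")
    fn = fns[metric]
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    values = np.full((grid1.size, grid2.size), np.nan)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            p, q = _AXIS_SETTERS[name1](params, pools, v1)
            p, q = _AXIS_SETTERS[name2](p, q, v2)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values[i, j] = fn(p, q)
            except (basic_analytic.DomainError, basic_analytic.DegenerateBoundary,
                    ValueError):
                pass
    return ScanResult(name1, name2, grid1, grid2, metric, values, threshold)
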
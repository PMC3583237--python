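"""Exact steady state of the basic PDC and derived response metrics.

At steady state the two Michaelis relations M1[SpP] = [Sp][P] and
M2[SK] = [S][K], the flux balance k1[SpP] = k2[SK] (hence [SpP] = alpha[SK]
with alpha = k2/k1) and the conservation laws reduce the basic cycle to a
single cubic in the kinase-substrate complex concentration [SK]:

    [SK]^3 + Q1 [SK]^2 + Q2 [SK] + Q3 = 0

with Q1 = -Kt + v1, Q2 = u1 Kt + v2, Q3 = u2 Kt and

    u1 = Pt/alpha + (M1 + St)/(alpha + 1)
    u2 = -Pt St / (alpha (alpha + 1))
    v1 = -Pt/alpha - (M1 + M2 + St)/(alpha + 1)
    v2 = Pt (M2 + St) / (alpha (alpha + 1))

(derived symbolically from the steady-state relations; the package's tests
cross-check every root against full-ODE relaxation).  The admissible root
satisfies 0 <= [SK] <= min(Kt, St) and alpha[SK] < Pt, from which the
phosphorylated fraction is

    R = (alpha [SK] / St) (M1 / (Pt - alpha [SK]) + 1).

As Kt -> infinity the cubic degenerates to a quadratic whose admissible root
SK_inf = (u1 - sqrt(u1^2 + 4 u2))/2 yields the asymptotic plateau R_inf,
which can be strictly below one: the phosphatase sequesters substrate and
full phosphorylation is never reached.  Hill numbers are computed with the
response-coefficient formula nH = log(81)/log(Kt90/Kt10) where the 10%/90%
levels are taken relative to R_inf, not to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .model_core import DerivedConstants, Pools, RateParams, derive_constants

__all__ = [
    "CubicCoefficients",
    "AsymptoteResult",
    "HillResult",
    "DomainError",
    "DegenerateBoundary",
    "cubic_coefficients",
    "solve_sk",
    "r_from_sk",
    "sk_inf_kt",
    "r_inf_st",
    "sk_from_r",
    "kt_from_sk",
    "hill_number_analytic",
    "hill_number_fit",
]


class DomainError(ValueError):
    """An argument violates the admissibility conditions of the steady state."""


class DegenerateBoundary(ValueError):
    """Pt/alpha == Kt: the large-St limit of R is discontinuous here."""


def _abc(params: RateParams, pools: Pools) -> tuple[float, float, float]:
    dc = derive_constants(params)
    if dc.alpha is None:
        raise DomainError("alpha undefined: k1 must be > 0")
    if dc.M1 is None or dc.M2 is None:
        raise DomainError("M1 and M2 require lambda1, lambda2 > 0")
    return dc.alpha, dc.M1, dc.M2


@dataclass(frozen=True)
class CubicCoefficients:
    Q1: float
    Q2: float
    Q3: float
    u1: float
    u2: float
    v1: float
    v2: float


def cubic_coefficients(params: RateParams, pools: Pools) -> CubicCoefficients:
    """Coefficients of the monic steady-state cubic in [SK]."""
    a, M1, M2 = _abc(params, pools)
    Pt, St, Kt = pools.Pt, pools.St, pools.Kt
    u1 = Pt / a + (M1 + St) / (a + 1)
    u2 = -Pt * St / (a * (a + 1))
    v1 = -Pt / a - (M1 + M2 + St) / (a + 1)
    v2 = Pt * (M2 + St) / (a * (a + 1))
    return CubicCoefficients(
        Q1=-Kt + v1, Q2=u1 * Kt + v2, Q3=u2 * Kt, u1=u1, u2=u2, v1=v1, v2=v2
    )


def _admissible_roots(coeffs: CubicCoefficients, a, Pt, St, Kt):
    roots = np.roots([1.0, coeffs.Q1, coeffs.Q2, coeffs.Q3])
    upper = min(Kt, St)
    out = []
    for r in roots:
        if abs(r.imag) > 1e-9 * max(1.0, abs(r)):
            continue
        x = float(r.real)
        if -1e-12 * max(1.0, upper) <= x <= upper * (1 + 1e-9) and (
            Pt == 0 or a * x < Pt * (1 - 1e-9)
        ):
            out.append(min(max(x, 0.0), upper))
    return roots, out


def solve_sk(params: RateParams, pools: Pools) -> float:
    """The admissible steady-state [SK] (uM), polished to machine residual."""
    a, M1, M2 = _abc(params, pools)
    Pt, St, Kt = pools.Pt, pools.St, pools.Kt
    if Kt == 0 or St == 0:
        return 0.0
    c = cubic_coefficients(params, pools)
    roots, adm = _admissible_roots(c, a, Pt, St, Kt)

    def cubic(x):
        return ((x + c.Q1) * x + c.Q2) * x + c.Q3

    if not adm:
        raise DomainError(f"no admissible root among {roots!r}")
    if len(adm) > 1:
        warnings.warn(
            f"multiple near-admissible roots {adm}; taking minimal |residual|",
            stacklevel=2,
        )
        adm.sort(key=lambda x: abs(cubic(x)))
    x = adm[0]
    # bracketed polish: the companion-matrix root can lose digits at extreme
    # parameter ratios (St/Pt up to 1e4 in the printed scans)
    scale = max(abs(c.Q1), abs(c.Q2), abs(c.Q3), 1.0)
    if abs(cubic(x)) > 1e-12 * scale:
        h = max(1e-9 * max(x, 1.0), abs(cubic(x)) / scale)
        lo, hi = max(x - h, 0.0), min(x + h, min(Kt, St))
        for _ in range(60):
            if cubic(lo) * cubic(hi) < 0:
                x = brentq(cubic, lo, hi, xtol=1e-15, rtol=1e-15)
                break
            h *= 2.0
            lo, hi = max(x - h, 0.0), min(x + h, min(Kt, St))
    return float(x)


def r_from_sk(sk: float, params: RateParams, pools: Pools) -> float:
    """Phosphorylated fraction R from the steady-state [SK]."""
    a, M1, _ = _abc(params, pools)
    if pools.St <= 0:
        raise DomainError("St must be > 0 to define R")
    if a * sk >= pools.Pt:
        raise DomainError(f"alpha*[SK] = {a * sk:.6g} must be < Pt = {pools.Pt:.6g}")
    return float(a * sk / pools.St * (M1 / (pools.Pt - a * sk) + 1.0))


@dataclass(frozen=True)
class AsymptoteResult:
    SK_inf: float
    R_inf: float
    limit: str  # "Kt" or "St"


def sk_inf_kt(params: RateParams, pools: Pools) -> AsymptoteResult:
    """Large-Kt limit of ([SK], R); independent of the kinase constants M2."""
    a, M1, _ = _abc(params, pools)
    Pt, St = pools.Pt, pools.St
    u1 = Pt / a + (M1 + St) / (a + 1)
    u2 = -Pt * St / (a * (a + 1))
    # (u1 - sqrt(u1^2 + 4 u2))/2 rationalized: the direct form loses ~half
    # the mantissa when |u2| << u1^2 (e.g. St/Pt ~ 1e8 scans)
    sk = -2 * u2 / (u1 + np.sqrt(u1 * u1 + 4 * u2))
    if St == 0:
        return AsymptoteResult(0.0, 0.0, "Kt")
    return AsymptoteResult(float(sk), r_from_sk(float(sk), params, pools), "Kt")


def r_inf_st(params: RateParams, pools: Pools) -> AsymptoteResult:
    """Large-St limit of R: 1 if Pt/alpha < Kt (kinase wins), else 0."""
    a, _, _ = _abc(params, pools)
    ratio = pools.Pt / a
    if np.isclose(ratio, pools.Kt, rtol=1e-12, atol=0.0):
        raise DegenerateBoundary(
            f"Pt/alpha == Kt == {pools.Kt:.6g}: large-St limit is discontinuous"
        )
    if ratio < pools.Kt:
        return AsymptoteResult(float(ratio), 1.0, "St")
    return AsymptoteResult(float(pools.Kt), 0.0, "St")


def sk_from_r(R: float, params: RateParams, pools: Pools) -> float:
    """Invert R([SK]): the smaller quadratic branch keeps alpha[SK] < Pt."""
    a, M1, _ = _abc(params, pools)
    Pt, St = pools.Pt, pools.St
    b = M1 + Pt + R * St
    disc = b * b - 4 * R * St * Pt
    if disc < 0:
        raise DomainError(f"negative discriminant for R={R!r}")
    return float((b - np.sqrt(disc)) / (2 * a))


def kt_from_sk(sk: float, params: RateParams, pools: Pools) -> float:
    """Total kinase that places the steady state at the given [SK].

    The steady-state cubic is linear in Kt, so Kt = (sk^3 + v1 sk^2 + v2 sk)
    / (sk^2 - u1 sk - u2); the denominator vanishes exactly at SK_inf, where
    the required Kt diverges.  Only 0 <= [SK] < SK_inf is invertible: beyond
    the asymptote no finite kinase pool reaches the requested complex level.
    """
    a, M1, _ = _abc(params, pools)
    if sk < 0 or a * sk >= pools.Pt:
        raise DomainError(f"[SK]={sk!r} violates 0 <= alpha[SK] < Pt")
    sk_lim = sk_inf_kt(params, pools).SK_inf
    if sk >= sk_lim:
        raise DomainError(
            f"[SK]={sk!r} is at or beyond the large-Kt asymptote {sk_lim!r}"
        )
    c = cubic_coefficients(params, pools)
    den = sk * sk - c.u1 * sk - c.u2
    kt = (sk ** 3 + c.v1 * sk * sk + c.v2 * sk) / den
    if kt < 0:
        raise DomainError(f"no non-negative Kt reproduces [SK]={sk!r}")
    return float(kt)


@dataclass(frozen=True)
class HillResult:
    nH: float
    R_inf: float
    R10: float
    R90: float
    SK10: float
    SK90: float
    Kt10: float
    Kt90: float


def hill_number_analytic(params: RateParams, pools: Pools) -> HillResult:
    """Response-coefficient Hill number of the analytic R(Kt) curve.

    The 10% and 90% levels are fractions of the plateau R_inf (which may be
    well below 1), so partial asymptotic phosphorylation does not inflate nH.
    """
    asym = sk_inf_kt(params, pools)
    if asym.R_inf <= 0:
        raise DomainError("R_inf must be > 0 for a Hill number")
    R10, R90 = 0.1 * asym.R_inf, 0.9 * asym.R_inf
    sk10 = sk_from_r(R10, params, pools)
    sk90 = sk_from_r(R90, params, pools)
    kt10 = kt_from_sk(sk10, params, pools)
    kt90 = kt_from_sk(sk90, params, pools)
    return HillResult(
        nH=float(np.log(81.0) / np.log(kt90 / kt10)),
        R_inf=asym.R_inf, R10=R10, R90=R90,
        SK10=sk10, SK90=sk90, Kt10=kt10, Kt90=kt90,
    )


def hill_number_fit(
    params: RateParams,
    pools: Pools,
    kt_grid=None,
) -> float:
    """Hill exponent from fitting R_inf * Kt^n / (K^n + Kt^n) to the curve.

    Cross-check for the response-coefficient formula; the plateau is fixed at
    the analytic R_inf so only (K, n) are free.
    """
    asym = sk_inf_kt(params, pools)
    if kt_grid is None:
        kt_grid = np.logspace(-3, 4, 400)
    R = np.array(
        [r_from_sk(solve_sk(params, pools.replace(Kt=kt)), params, pools) for kt in kt_grid]
    )

    def hill(x, K, n):
        return asym.R_inf / (1.0 + (K / x) ** n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(hill, kt_grid, R, p0=[np.median(kt_grid), 1.5], maxfev=20000)
    return float(popt[1])
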
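"""Total quasi-steady-state approximation of the phosphatase-active model.

The tQSSA takes as slow variables the *total* phosphorylated substrate
outside the enzyme pair complex, A = [Sp] + C1, and the total enzyme-pair
concentration X = C2 + C4, where C1 = [SpP], C2 = [SpPK], C3 = [SK] and
C4 = [PK].  Treating the intermediate complexes as fast, they satisfy the
coupled relations

    M1 C1 = (A - C1)(Pt - C1 - X)
    M3 C2 = (A - C1)(X - C2)
    M2 C3 = (St - A - C2 - C3)(Kt - C3 - X)

which are solved exactly in one pass: the C1 relation is a standalone
quadratic in C1 given (A, X); C2 is then linear; C3 a quadratic given C2.
The slow dynamics are

    dX/dt = kappa1 (Pt - C1 - X)(Kt - C3 - X) - kappa_m1 (X - C2)
    dA/dt = -k1 C1 + k2 C3 - k3 C2

These equations encode phosphatase activity of the complex (the -k3 C2 sink);
the module therefore refuses variants with an active complex-kinase arm
rather than silently extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .model_core import ModelVariant, Pools, RateParams, derive_constants

__all__ = ["SlowState", "ComplexSolution", "solve_complexes", "tqssa_rhs",
           "tqssa_steady_state", "TqssaError"]

RESIDUAL_TOL = 1e-10  # uM^2, per complex relation

_ALLOWED = (ModelVariant.COMPLEX_P_ACTIVE, ModelVariant.COMPLEX_INACTIVE,
            ModelVariant.BASIC)


class TqssaError(ValueError):
    pass


def _check_variant(variant: ModelVariant) -> None:
    if ModelVariant(variant) not in _ALLOWED:
        raise TqssaError(
            "tQSSA reduction is formulated for the phosphatase-active complex "
            f"(or its no-complex limits); got {ModelVariant(variant).value!r}"
        )


@dataclass(frozen=True)
class SlowState:
    A: float  # total phosphorylated substrate outside PK complex, uM
    X: float  # total PK concentration (free + substrate-bound), uM


@dataclass(frozen=True)
class ComplexSolution:
    C1: float
    C2: float
    C3: float
    residuals: tuple[float, float, float]


def _minus_branch(b: float, c: float) -> float:
    """Smaller root of x^2 - b x + c = 0, continuous with the c -> 0 limit."""
    disc = b * b - 4 * c
    if disc < 0:
        if disc > -1e-12 * max(b * b, 1.0):
            disc = 0.0
        else:
            raise TqssaError(f"complex quadratic has no real root (b={b}, c={c})")
    return (b - np.sqrt(disc)) / 2


def solve_complexes(
    slow: SlowState, params: RateParams, pools: Pools, check: bool = True
) -> ComplexSolution:
    """Exact fast-complex concentrations at given slow variables (A, X).

    With ``check=False`` mildly unphysical (A, X) are evaluated anyway; the
    steady-state sweep uses this so the root finder can cross bounds on its
    way to the physical solution.
    """
    dc = derive_constants(params)
    M1, M2 = dc.M1, dc.M2
    if M1 is None or M2 is None:
        raise TqssaError("M1 and M2 must be defined")
    A, X = slow.A, slow.X
    Pt, Kt, St = pools.Pt, pools.Kt, pools.St
    if check:
        slack = 1e-6 * max(St, Pt, Kt, 1.0)
        if not (-slack <= A <= St + slack) or not (-slack <= X <= min(Pt, Kt) + slack):
            raise TqssaError(f"slow state (A={A}, X={X}) outside conservation bounds")

    C1 = _minus_branch(A + (Pt - X) + M1, A * (Pt - X))
    if params.lambda3 > 0:
        M3 = dc.M3
        C2 = (A - C1) * X / (M3 + A - C1)
    else:
        C2 = 0.0
    S_avail = St - A - C2
    C3 = _minus_branch(S_avail + (Kt - X) + M2, S_avail * (Kt - X))

    r1 = M1 * C1 - (A - C1) * (Pt - C1 - X)
    r2 = (dc.M3 * C2 - (A - C1) * (X - C2)) if params.lambda3 > 0 else 0.0
    r3 = M2 * C3 - (S_avail - C3) * (Kt - C3 - X)
    return ComplexSolution(float(C1), float(C2), float(C3),
                           (float(r1), float(r2), float(r3)))


def tqssa_rhs(
    slow: SlowState, params: RateParams, pools: Pools, check: bool = True
) -> tuple[float, float]:
    """(dA/dt, dX/dt) of the reduced slow system."""
    c = solve_complexes(slow, params, pools, check=check)
    dX = (params.kappa1 * (pools.Pt - c.C1 - slow.X) * (pools.Kt - c.C3 - slow.X)
          - params.kappa_m1 * (slow.X - c.C2))
    dA = -params.k1 * c.C1 + params.k2 * c.C3 - params.k3 * c.C2
    return float(dA), float(dX)


def tqssa_steady_state(
    params: RateParams,
    pools: Pools,
    kt_grid,
    variant: ModelVariant = ModelVariant.COMPLEX_P_ACTIVE,
):
    """Reduced-model steady-state R over a Kt grid (continuation sweep).

    Returns (R array, A array, X array).  R counts every phosphorylated
    species: R = (A + C2)/St.  Starting values for each grid point are the
    solution at the previous one; the first point starts cold at ~zero.
    """
    _check_variant(variant)
    kt_grid = np.asarray(kt_grid, dtype=float)
    Rs = np.full(kt_grid.shape, np.nan)
    As = np.full(kt_grid.shape, np.nan)
    Xs = np.full(kt_grid.shape, np.nan)
    guess = np.array([min(1e-9, pools.St), 1e-9])

    def fun(z, kt):
        return tqssa_rhs(SlowState(z[0], z[1]), params, pools.replace(Kt=kt),
                         check=False)

    no_complex = params.kappa1 == 0.0

    for i, kt in enumerate(kt_grid):
        if kt == 0.0:
            Rs[i], As[i], Xs[i] = 0.0, 0.0, 0.0
            guess = np.array([1e-9, 1e-9])
            continue
        if no_complex:
            # kappa1 = 0: X = 0 identically and dX/dt vanishes, so the 2-D
            # system is singular; the remaining scalar balance dA/dt = 0 is
            # monotone in A and bracketed on [0, St]
            def dA(a, kt=kt):
                return tqssa_rhs(SlowState(a, 0.0), params,
                                 pools.replace(Kt=kt), check=False)[0]

            if dA(0.0) <= 0:
                A = 0.0
            elif dA(pools.St) >= 0:
                A = pools.St
            else:
                A = brentq(dA, 0.0, pools.St, xtol=1e-15, rtol=8.9e-16)
            Rs[i], As[i], Xs[i] = (A / pools.St if pools.St > 0 else 0.0), A, 0.0
            continue
        sol = None
        for start in (guess, np.array([1e-6 * pools.St, 1e-6 * min(pools.Pt, kt)]),
                      np.array([0.5 * pools.St, 0.5 * min(pools.Pt, kt)])):
            cand = root(fun, start, args=(kt,), method="hybr", tol=1e-13)
            if cand.success:
                sol = cand
                break
        if sol is None:
            continue  # flagged as NaN; sweep goes on
        A = min(max(sol.x[0], 0.0), pools.St)
        X = min(max(sol.x[1], 0.0), min(pools.Pt, kt))
        c = solve_complexes(SlowState(A, X), params, pools.replace(Kt=kt))
        Rs[i] = (A + c.C2) / pools.St if pools.St > 0 else 0.0
        As[i], Xs[i] = A, X
        guess = np.array([max(A, 1e-9), max(X, 1e-9)])
    return Rs, As, Xs


def qssa_steady_state(params: RateParams, pools: Pools, kt_grid):
    """Naive (free-substrate) QSSA steady-state R over a Kt grid.

    Enzymes partition between P, K and PK through the dissociation constant
    omega while substrate-bound enzyme is neglected, and the substrate obeys
    Michaelis-Menten flux balance on its free forms.  Kept as the weaker
    reference approximation: it cannot reproduce the bell-shaped response.
    """
    dc = derive_constants(params)
    M1, M2, M3 = dc.M1, dc.M2, dc.M3
    out = np.full(np.shape(kt_grid), np.nan)
    for i, kt in enumerate(np.asarray(kt_grid, dtype=float)):
        Pt, St = pools.Pt, pools.St
        if params.kappa1 > 0:
            w = params.kappa_m1 / params.kappa1
            b = Pt + kt + w
            PK = (b - np.sqrt(b * b - 4 * Pt * kt)) / 2
        else:
            PK = 0.0
        P, K = Pt - PK, kt - PK

        def balance(sp):
            s = St - sp
            v_k = params.k2 * K * s / (M2 + s)
            v_p = params.k1 * P * sp / (M1 + sp)
            if params.k3 > 0 and M3 is not None:
                v_p += params.k3 * PK * sp / (M3 + sp)
            return v_k - v_p

        lo, hi = 0.0, pools.St
        if balance(lo) <= 0:
            out[i] = 0.0
            continue
        if balance(hi) >= 0:
            out[i] = 1.0
            continue
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if balance(mid) > 0:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi) / St
    return out
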
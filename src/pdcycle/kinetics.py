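"""Mass-action kinetics of the basic and extended PDC models.

The basic cycle tracks four species (S, Sp, SpP, SK); free enzymes follow
from conservation (Kt = [K] + [SK], Pt = [P] + [SpP]).  The extended model
tracks all nine species explicitly, including the enzyme complex PK and the
ternary complexes SpPK and SPK.  Note that both ternary complexes contain
both enzymes, so the conserved totals are

    Pt = [P] + [SpP] + [SpPK] + [SPK] + [PK]
    Kt = [K] + [SK] + [SpPK] + [SPK] + [PK]
    St = [S] + [Sp] + [SpP] + [SK] + [SpPK] + [SPK]

and the mass-action right-hand side preserves all three exactly.

Steady states are found by stiff relaxation followed by a Newton polish on
the conservation-reduced system; the extended model has no closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import ModelVariant, ParameterError, Pools, RateParams, validate_variant

__all__ = [
    "BASIC_SPECIES",
    "EXTENDED_SPECIES",
    "Trajectory",
    "SteadyState",
    "SteadyStateError",
    "species_names",
    "default_y0",
    "rhs_basic",
    "rhs_extended",
    "integrate",
    "steady_state_numeric",
    "transient_time",
    "conservation_error",
    "phosphorylated_fraction",
]

BASIC_SPECIES = ("S", "Sp", "SpP", "SK")
EXTENDED_SPECIES = ("S", "Sp", "SpP", "SK", "P", "K", "PK", "SpPK", "SPK")

# default solver tolerances; rates in the shipped fixtures span 0.01-500 1/s
RTOL = 1e-10
ATOL = 1e-12
RESIDUAL_TOL = 1e-10  # uM/s, max-norm contract for a converged steady state


class SteadyStateError(RuntimeError):
    """Relaxation/Newton failed to meet the residual contract."""


def species_names(variant: ModelVariant) -> tuple[str, ...]:
    return BASIC_SPECIES if ModelVariant(variant) is ModelVariant.BASIC else EXTENDED_SPECIES


def default_y0(pools: Pools, variant: ModelVariant) -> np.ndarray:
    """Unphosphorylated start: all substrate free as S, all enzymes free."""
    if ModelVariant(variant) is ModelVariant.BASIC:
        return np.array([pools.St, 0.0, 0.0, 0.0])
    y0 = np.zeros(9)
    y0[0] = pools.St
    y0[4] = pools.Pt
    y0[5] = pools.Kt
    return y0


def rhs_basic(state, params: RateParams, pools: Pools) -> np.ndarray:
    """Time derivatives of (S, Sp, SpP, SK); free P, K from conservation."""
    if pools.Pt < 0 or pools.Kt < 0:
        raise ParameterError("pools must be non-negative")
    S, Sp, SpP, SK = state
    P = pools.Pt - SpP
    K = pools.Kt - SK
    p = params
    bind1 = p.lambda1 * Sp * P
    bind2 = p.lambda2 * S * K
    dSp = p.lambda_m1 * SpP + p.k2 * SK - bind1
    dSpP = -(p.lambda_m1 + p.k1) * SpP + bind1
    dS = p.lambda_m2 * SK + p.k1 * SpP - bind2
    dSK = -(p.lambda_m2 + p.k2) * SK + bind2
    return np.array([dS, dSp, dSpP, dSK])


def rhs_extended(
    state, params: RateParams, pools: Pools, recruitment_rate: float = 0.0
) -> np.ndarray:
    """Time derivatives of all nine species of the extended model.

    ``recruitment_rate`` (uM/s) adds a constant source of free kinase, used by
    the linear-recruitment scenario; it is the only term that breaks kinase
    conservation (by exactly that rate).
    """
    if pools.Pt < 0 or pools.Kt < 0:
        raise ParameterError("pools must be non-negative")
    S, Sp, SpP, SK, P, K, PK, SpPK, SPK = state
    p = params
    bind1 = p.lambda1 * Sp * P
    bind2 = p.lambda2 * S * K
    bind3 = p.lambda3 * Sp * PK
    bind4 = p.lambda4 * S * PK
    bindc = p.kappa1 * P * K
    dSp = (p.lambda_m1 * SpP + p.k2 * SK - bind1
           + p.lambda_m3 * SpPK - bind3 + p.k4 * SPK)
    dSpP = -(p.lambda_m1 + p.k1) * SpP + bind1
    dS = (p.lambda_m2 * SK + p.k1 * SpP - bind2
          + p.k3 * SpPK + p.lambda_m4 * SPK - bind4)
    dSK = -(p.lambda_m2 + p.k2) * SK + bind2
    dPK = (bindc - p.kappa_m1 * PK
           + (p.lambda_m3 + p.k3) * SpPK - bind3
           + (p.lambda_m4 + p.k4) * SPK - bind4)
    dSpPK = bind3 - (p.lambda_m3 + p.k3) * SpPK
    dSPK = bind4 - (p.lambda_m4 + p.k4) * SPK
    dP = (p.lambda_m1 + p.k1) * SpP - bind1 - bindc + p.kappa_m1 * PK
    dK = ((p.lambda_m2 + p.k2) * SK - bind2 - bindc + p.kappa_m1 * PK
          + recruitment_rate)
    return np.array([dS, dSp, dSpP, dSK, dP, dK, dPK, dSpPK, dSPK])


def _rhs(variant: ModelVariant):
    if ModelVariant(variant) is ModelVariant.BASIC:
        return lambda t, y, p, pools: rhs_basic(y, p, pools)
    return lambda t, y, p, pools: rhs_extended(y, p, pools)


def phosphorylated_fraction(y, variant: ModelVariant, St: float) -> np.ndarray:
    """R = total phosphorylated substrate / St (includes all Sp-containing species)."""
    y = np.asarray(y)
    if St == 0:
        return np.zeros(y.shape[1:]) if y.ndim > 1 else 0.0
    if ModelVariant(variant) is ModelVariant.BASIC:
        return (y[1] + y[2]) / St
    return (y[1] + y[2] + y[7]) / St


def conservation_error(y, params: RateParams, pools: Pools, variant: ModelVariant) -> dict[str, float]:
    """Max absolute drift of each conserved total along a trajectory (uM)."""
    y = np.atleast_2d(np.asarray(y).T).T  # (nspecies, nt)
    if ModelVariant(variant) is ModelVariant.BASIC:
        s_tot = y[0] + y[1] + y[2] + y[3]
        return {
            "St": float(np.max(np.abs(s_tot - pools.St))),
            "Kt": 0.0,  # eliminated by construction
            "Pt": 0.0,
        }
    s_tot = y[0] + y[1] + y[2] + y[3] + y[7] + y[8]
    p_tot = y[4] + y[2] + y[6] + y[7] + y[8]
    k_tot = y[5] + y[3] + y[6] + y[7] + y[8]
    return {
        "St": float(np.max(np.abs(s_tot - pools.St))),
        "Pt": float(np.max(np.abs(p_tot - pools.Pt))),
        "Kt": float(np.max(np.abs(k_tot - pools.Kt))),
    }


@dataclass
class Trajectory:
    """A time course with dense output retained for event/peak detection."""

    t: np.ndarray
    y: np.ndarray  # (n_species, n_times)
    species: tuple[str, ...]
    params: RateParams
    pools: Pools
    variant: ModelVariant
    sol: object = field(default=None, repr=False)  # scipy OdeSolution
    nsteps: int = 0

    @property
    def R(self) -> np.ndarray:
        return phosphorylated_fraction(self.y, self.variant, self.pools.St)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.y.T, columns=list(self.species))
        df.insert(0, "time_s", self.t)
        df["R"] = self.R
        return df


@dataclass
class SteadyState:
    state: np.ndarray
    species: tuple[str, ...]
    residual: float  # max-norm of the RHS, uM/s
    R: float
    converged: bool


def integrate(
    params: RateParams,
    pools: Pools,
    variant: ModelVariant,
    t_end: float,
    y0=None,
    n_points: int = 201,
    method: str = "LSODA",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model to ``t_end`` with a stiff-capable solver."""
    variant = ModelVariant(variant)
    params, _ = validate_variant(params, variant)
    y0 = default_y0(pools, variant) if y0 is None else np.asarray(y0, dtype=float)
    names = species_names(variant)
    if len(y0) != len(names):
        raise ParameterError(f"y0 must have {len(names)} entries for {variant.value}")
    if t_end == 0:
        return Trajectory(np.array([0.0]), y0[:, None], names, params, pools, variant)
    fun = _rhs(variant)
    sol = solve_ivp(
        fun, (0.0, t_end), y0, args=(params, pools),
        method=method, rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise SteadyStateError(f"solver failed at t={sol.t[-1]:.6g}: {sol.message}")
    t = np.linspace(0.0, t_end, n_points)
    y = sol.sol(t)
    return Trajectory(t, y, names, params, pools, variant, sol=sol.sol, nsteps=sol.t.size)


def _free_indices(params: RateParams, variant: ModelVariant) -> list[int]:
    """Reduced coordinates with live dynamics.

    A complex species whose formation and decay rates are all zero is frozen
    at its initial value (its ODE is identically zero); including it in the
    Newton polish would leave a singular direction.
    """
    if variant is ModelVariant.BASIC:
        return [1, 2, 3]
    idx = [1, 2, 3]
    complex_live = (params.kappa1 > 0 or params.kappa_m1 > 0
                    or params.lambda3 > 0 or params.lambda_m3 + params.k3 > 0
                    or params.lambda4 > 0 or params.lambda_m4 + params.k4 > 0)
    if complex_live:
        idx.append(6)  # PK
    if params.lambda3 > 0 or params.lambda_m3 + params.k3 > 0:
        idx.append(7)  # SpPK
    if params.lambda4 > 0 or params.lambda_m4 + params.k4 > 0:
        idx.append(8)  # SPK
    return idx


def _reduced_residual(z, y_ref, idx, params, pools, variant):
    """RHS on free coordinates; conserved totals and frozen species eliminated."""
    y = _full_state(z, y_ref, idx, pools, variant)
    if variant is ModelVariant.BASIC:
        return rhs_basic(y, params, pools)[idx]
    return rhs_extended(y, params, pools)[idx]


def _full_state(z, y_ref, idx, pools, variant):
    """Rebuild the full state from free coordinates ``z`` at positions ``idx``;
    frozen species keep their ``y_ref`` values, free enzymes/substrate follow
    from conservation."""
    if variant is ModelVariant.BASIC:
        y = np.array(y_ref, dtype=float)
        y[idx] = z
        y[0] = pools.St - y[1] - y[2] - y[3]
        return y
    y = np.array(y_ref, dtype=float)
    y[idx] = z
    Sp, SpP, SK, PK, SpPK, SPK = y[1], y[2], y[3], y[6], y[7], y[8]
    y[0] = pools.St - Sp - SpP - SK - SpPK - SPK
    y[4] = pools.Pt - SpP - PK - SpPK - SPK
    y[5] = pools.Kt - SK - PK - SpPK - SPK
    return y


def steady_state_numeric(
    params: RateParams,
    pools: Pools,
    variant: ModelVariant,
    y0=None,
    residual_tol: float = RESIDUAL_TOL,
    t_max: float = 1e9,
) -> SteadyState:
    """Relax to equilibrium, then Newton-polish on the reduced system.

    Raises :class:`SteadyStateError` rather than returning a silent partial
    result if the residual contract cannot be met within the time budget.
    """
    variant = ModelVariant(variant)
    params, _ = validate_variant(params, variant)
    y0 = default_y0(pools, variant) if y0 is None else np.asarray(y0, dtype=float)
    fun = _rhs(variant)
    names = species_names(variant)
    # the absolute contract is reachable for O(1 uM) pools; for very large
    # pools the mass-action fluxes are so large that double-precision
    # round-off alone exceeds it, so the tolerance scales with the pools
    residual_tol = residual_tol * max(1.0, pools.Kt, pools.Pt, pools.St)

    # crude time scale from the fastest first-order rate; relax in doublings
    rate_scale = max(
        params.k1, params.k2, params.lambda_m1, params.lambda_m2,
        params.kappa_m1, params.k3, params.k4, 1e-3,
    )
    t_end = 10.0 / rate_scale
    y = y0.copy()
    for _ in range(60):
        t_end = min(t_end * 8.0, t_max)
        sol = solve_ivp(
            fun, (0.0, t_end), y, args=(params, pools),
            method="LSODA", rtol=1e-8, atol=1e-11,
        )
        if not sol.success:
            # LSODA occasionally stalls on extreme pool ratios; BDF is slower
            # but sturdier there
            sol = solve_ivp(
                fun, (0.0, t_end), y, args=(params, pools),
                method="BDF", rtol=1e-8, atol=1e-11,
            )
        if not sol.success:
            raise SteadyStateError(f"relaxation failed: {sol.message}")
        y = sol.y[:, -1]
        # Newton polish from the relaxed point
        idx = _free_indices(params, variant)
        res = root(
            _reduced_residual, y[idx], args=(y, idx, params, pools, variant),
            method="hybr", tol=1e-13,
        )
        cand = _full_state(res.x, y, idx, pools, variant)
        resid = float(np.max(np.abs(fun(0.0, cand, params, pools))))
        if res.success and resid < residual_tol and cand.min() > -1e-9:
            cand = np.clip(cand, 0.0, None)
            return SteadyState(
                cand, names, resid,
                float(phosphorylated_fraction(cand, variant, pools.St)),
                True,
            )
        if t_end >= t_max:
            break
    raise SteadyStateError(
        f"no steady state within budget (last residual {resid:.3g} uM/s)"
    )


def transient_time(
    params: RateParams,
    pools: Pools,
    variant: ModelVariant,
    y0=None,
    tol: float = 1e-4,
    t_max: float = 1e7,
    n_sample: int = 20001,
) -> float:
    """Smallest time after which |R(t) - R_ss| stays below ``tol``.

    The trajectory is sampled on a uniform grid of the dense solver output;
    the returned time is the first sample after the last excursion, refined
    by bisection between the bracketing samples.
    """
    variant = ModelVariant(variant)
    ss = steady_state_numeric(params, pools, variant, y0=y0)
    y0 = default_y0(pools, variant) if y0 is None else np.asarray(y0, dtype=float)
    # expand the window until the endpoint has settled
    t_end = 10.0
    while t_end <= t_max:
        traj = integrate(params, pools, variant, t_end, y0=y0, n_points=n_sample)
        dev = np.abs(traj.R - ss.R)
        if dev[-1] < tol and dev[int(0.9 * n_sample):].max() < tol:
            break
        t_end *= 10.0
    else:
        raise SteadyStateError("R(t) did not settle within the time budget")
    bad = np.nonzero(dev >= tol)[0]
    if bad.size == 0:
        return 0.0
    lo, hi = traj.t[bad[-1]], traj.t[bad[-1] + 1]
    St = pools.St
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        r = float(phosphorylated_fraction(traj.sol(mid), variant, St))
        if abs(r - ss.R) >= tol:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(hi, 1.0):
            break
    return float(hi)
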
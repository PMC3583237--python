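"""Transient phosphoinositide-regulation scenarios.

Two mechanisms by which a kinase-phosphatase pair with a phosphatase-active
complex can produce a transient pulse of phosphorylated lipid on a maturing
endosome:

* **Linear kinase recruitment** — the kinase is delivered to the membrane at
  a constant rate (total kinase Kt(t) = rate * t) against a fixed phosphatase
  pool.  As Kt sweeps through the bell-shaped dose-response, R(t) rises and
  then falls without any additional trigger.
* **Triggered activity switch** — fixed enzyme pools, but at a set time a
  signalling event flips the complex's activity from kinase to phosphatase.
  R(t) rises while the complex phosphorylates and collapses after the switch.

At the switch the deactivated arm's association and catalysis stop, but the
complexes it already holds are not teleported: they drain through the
retained dissociation rate (a ``convert`` option instead re-labels them as
free complex instantly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    EXTENDED_SPECIES, SteadyStateError, Trajectory, phosphorylated_fraction,
    rhs_extended,
)
from .model_core import ModelVariant, ParameterError, Pools, RateParams

__all__ = ["ScenarioSpec", "TransientResult", "simulate_recruitment",
           "simulate_trigger", "peak_time"]


@dataclass(frozen=True)
class ScenarioSpec:
    params: RateParams
    pools: Pools
    variant: ModelVariant
    t_end: float
    recruitment_rate: float = 0.0  # uM/s, scenario (i)
    switch_time: float | None = None  # s, scenario (ii)
    post_switch: dict = field(default_factory=dict)  # rate overrides after switch
    bound_complex_fate: str = "drain"  # or "convert"

    def __post_init__(self) -> None:
        if self.recruitment_rate < 0:
            raise ParameterError("recruitment rate must be >= 0")
        if self.switch_time is not None and not (0 <= self.switch_time <= self.t_end):
            raise ParameterError("switch time must lie within the simulated window")


@dataclass
class TransientResult:
    trajectory: Trajectory
    R_peak: float
    t_peak: float
    R_end: float
    is_peak: bool  # False when the maximum sits at the window end


def _result(traj: Trajectory) -> TransientResult:
    t_pk, r_pk, interior = peak_time(traj)
    return TransientResult(traj, r_pk, t_pk, float(traj.R[-1]), interior)


def _integrate_ext(params, pools, y0, t0, t1, recruit, n_points):
    sol = solve_ivp(
        lambda t, y: rhs_extended(y, params, pools, recruitment_rate=recruit),
        (t0, t1), y0, method="LSODA", rtol=1e-10, atol=1e-12, dense_output=True,
    )
    if not sol.success:
        raise SteadyStateError(f"solver failed at t={sol.t[-1]:.6g}: {sol.message}")
    t = np.linspace(t0, t1, n_points)
    return t, sol.sol(t), sol.sol


def simulate_recruitment(spec: ScenarioSpec, n_points: int = 2001) -> TransientResult:
    """Scenario (i): constant-rate kinase recruitment into the free pool.

    Kinase arrives unbound: d[K]/dt gains a constant source, so the total
    kinase is exactly Kt(0) + rate * t while substrate and phosphatase stay
    conserved.
    """
    if ModelVariant(spec.variant) is not ModelVariant.COMPLEX_P_ACTIVE:
        raise ParameterError("recruitment scenario assumes the phosphatase-active complex")
    pools = spec.pools
    y0 = np.zeros(9)
    y0[0] = pools.St
    y0[4] = pools.Pt
    y0[5] = pools.Kt  # usually 0: recruitment starts from an empty membrane
    t, y, dense = _integrate_ext(
        spec.params, pools, y0, 0.0, spec.t_end, spec.recruitment_rate, n_points
    )
    traj = Trajectory(t, y, EXTENDED_SPECIES, spec.params, pools,
                      ModelVariant.COMPLEX_P_ACTIVE, sol=dense)
    return _result(traj)


def simulate_trigger(spec: ScenarioSpec, n_points: int = 2001) -> TransientResult:
    """Scenario (ii): complex activity switches from kinase to phosphatase.

    Piecewise integration with an exact restart at the switch time.  After
    the switch the kinase arm's association/catalysis are zeroed and the
    post-switch phosphatase-arm rates applied; substrate already bound via
    the kinase arm either drains at its retained dissociation rate (default)
    or is converted instantly to free S + PK (``bound_complex_fate="convert"``).
    """
    pools = spec.pools
    pre = spec.params
    y0 = np.zeros(9)
    y0[0] = pools.St
    y0[4] = pools.Pt
    y0[5] = pools.Kt

    if spec.switch_time is None or spec.switch_time >= spec.t_end:
        t, y, dense = _integrate_ext(pre, pools, y0, 0.0, spec.t_end, 0.0, n_points)
        traj = Trajectory(t, y, EXTENDED_SPECIES, pre, pools, spec.variant, sol=dense)
        return _result(traj)

    n1 = max(int(n_points * spec.switch_time / spec.t_end), 2)
    t1, y1, _ = _integrate_ext(pre, pools, y0, 0.0, spec.switch_time, 0.0, n1)

    post = pre.replace(lambda4=0.0, k4=0.0, **spec.post_switch)
    y_switch = y1[:, -1].copy()
    if spec.bound_complex_fate == "convert":
        y_switch[0] += y_switch[8]  # SPK -> S + PK
        y_switch[6] += y_switch[8]
        y_switch[8] = 0.0
    elif spec.bound_complex_fate != "drain":
        raise ParameterError("bound_complex_fate must be 'drain' or 'convert'")

    t2, y2, dense2 = _integrate_ext(
        post, pools, y_switch, spec.switch_time, spec.t_end, 0.0,
        max(n_points - n1, 2),
    )
    t = np.concatenate([t1, t2[1:]])
    y = np.concatenate([y1, y2[:, 1:]], axis=1)
    traj = Trajectory(t, y, EXTENDED_SPECIES, post, pools,
                      ModelVariant.COMPLEX_P_ACTIVE, sol=dense2)
    return _result(traj)


def peak_time(traj: Trajectory) -> tuple[float, float, bool]:
    """(t_peak, R_peak, interior) of a trajectory, refined on dense output.

    A maximum at the window end is returned with ``interior=False`` — it is
    the running maximum, not a genuine transient peak.
    """
    R = traj.R
    i = int(np.argmax(R))
    if i == len(R) - 1 or i == 0:
        return float(traj.t[i]), float(R[i]), False
    St = traj.pools.St
    lo, hi = traj.t[i - 1], traj.t[i + 1]
    if traj.sol is not None and traj.sol.t_min <= lo and hi <= traj.sol.t_max:
        # golden-section refinement of the dense-output maximum
        gr = (np.sqrt(5.0) - 1) / 2

        def r_of(t):
            return float(phosphorylated_fraction(traj.sol(t), traj.variant, St))

        a, b = lo, hi
        c, d = b - gr * (b - a), a + gr * (b - a)
        fc, fd = r_of(c), r_of(d)
        for _ in range(60):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = r_of(c)
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = r_of(d)
            if b - a < 1e-6 * max(b, 1.0):
                break
        t_pk = 0.5 * (a + b)
        return float(t_pk), r_of(t_pk), True
    return float(traj.t[i]), float(R[i]), True
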
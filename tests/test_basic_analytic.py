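"""Exact steady-state solution of the basic cycle.

Frozen expected values below were derived two independent ways: symbolic
expansion of the steady-state relations (Michaelis relations + flux balance
+ conservation) with sympy, and full-ODE relaxation of the mass-action
system; both agree to machine precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdcycle import ModelVariant, Pools, RateParams, fixture, kinetics
from pdcycle.basic_analytic import (
    DegenerateBoundary, DomainError, cubic_coefficients, hill_number_analytic,
    hill_number_fit, kt_from_sk, r_from_sk, r_inf_st, sk_from_r, sk_inf_kt,
    solve_sk,
)
from conftest import random_basic_set


class TestCubicCoefficients:
    def test_fig3b_frozen_oracle(self, fig3b):
        # alpha=1, M1=M2=2, Pt=1, St=100, Kt=10; symbolic-expansion oracle
        params, pools, _ = fig3b
        c = cubic_coefficients(params, pools.replace(Kt=10.0))
        assert c.u1 == pytest.approx(52.0)
        assert c.u2 == pytest.approx(-50.0)
        assert c.v1 == pytest.approx(-53.0)
        assert c.v2 == pytest.approx(51.0)
        assert c.Q1 == pytest.approx(-63.0)
        assert c.Q2 == pytest.approx(571.0)
        assert c.Q3 == pytest.approx(-500.0)

    def test_structure_relations(self, rng):
        # Q1 = -Kt + v1, Q2 = u1 Kt + v2, Q3 = u2 Kt, u2 <= 0, for random sets
        for _ in range(20):
            params, pools = random_basic_set(rng)
            c = cubic_coefficients(params, pools)
            assert c.Q1 == pytest.approx(-pools.Kt + c.v1)
            assert c.Q2 == pytest.approx(c.u1 * pools.Kt + c.v2)
            assert c.Q3 == pytest.approx(c.u2 * pools.Kt)
            assert c.u2 <= 0

    def test_no_substrate(self, fig3b):
        params, pools, _ = fig3b
        c = cubic_coefficients(params, pools.replace(St=0.0, Kt=5.0))
        assert c.u2 == 0.0
        assert solve_sk(params, pools.replace(St=0.0, Kt=5.0)) == 0.0

    def test_no_phosphatase(self, fig3b):
        params, pools, _ = fig3b
        p0 = pools.replace(Pt=0.0, Kt=5.0)
        c = cubic_coefficients(params, p0)
        alpha, M1 = 1.0, 2.0
        assert c.u1 == pytest.approx((M1 + p0.St) / (alpha + 1))
        assert c.u2 == 0.0

    def test_alpha_undefined(self, fig3b):
        params, pools, _ = fig3b
        with pytest.raises(DomainError):
            cubic_coefficients(params.replace(k1=0.0), pools)


class TestSolveSk:
    def test_no_kinase(self, fig3b):
        params, pools, _ = fig3b
        assert solve_sk(params, pools.replace(Kt=0.0)) == 0.0

    def test_matches_numeric_steady_state(self, fig3b):
        params, pools, _ = fig3b
        p = pools.replace(Kt=10.0)
        sk = solve_sk(params, p)
        ss = kinetics.steady_state_numeric(params, p, ModelVariant.BASIC)
        sk_numeric = ss.state[3]
        assert sk == pytest.approx(sk_numeric, rel=1e-6)

    def test_unique_admissible_root_random(self, rng):
        # brute-force root enumeration: exactly one root is physical
        for _ in range(100):
            params, pools = random_basic_set(rng)
            c = cubic_coefficients(params, pools)
            roots = np.roots([1.0, c.Q1, c.Q2, c.Q3])
            alpha = params.k2 / params.k1
            upper = min(pools.Kt, pools.St)
            adm = [
                r.real for r in roots
                if abs(r.imag) < 1e-9 * max(1, abs(r))
                and -1e-9 <= r.real <= upper * (1 + 1e-9)
                and alpha * r.real < pools.Pt * (1 - 1e-9)
            ]
            assert len(adm) == 1
            assert solve_sk(params, pools) == pytest.approx(adm[0], rel=1e-9, abs=1e-12)

    def test_polish_residual(self, rng):
        for _ in range(20):
            params, pools = random_basic_set(rng)
            c = cubic_coefficients(params, pools)
            x = solve_sk(params, pools)
            resid = ((x + c.Q1) * x + c.Q2) * x + c.Q3
            assert abs(resid) < 1e-10 * max(abs(c.Q1), abs(c.Q2), abs(c.Q3), 1.0)


class TestRFromSk:
    def test_zero(self, fig3b):
        params, pools, _ = fig3b
        assert r_from_sk(0.0, params, pools) == 0.0

    def test_fig3b_asymptote_value(self, fig3b):
        params, pools, _ = fig3b
        asym = sk_inf_kt(params, pools)
        assert asym.SK_inf == pytest.approx(0.98000799, rel=1e-6)
        assert asym.R_inf == pytest.approx(0.99019992, rel=1e-6)

    def test_domain_error_beyond_pt(self, fig3b):
        params, pools, _ = fig3b
        with pytest.raises(DomainError):
            r_from_sk(pools.Pt / 1.0 + 0.1, params, pools)  # alpha = 1

    def test_r_at_most_one_random(self, rng):
        for _ in range(200):
            params, pools = random_basic_set(rng)
            sk = solve_sk(params, pools)
            assert r_from_sk(sk, params, pools) <= 1.0 + 1e-12


class TestAsymptotes:
    def test_kt_asymptote_independent_of_kinase_constants(self, fig3b, rng):
        params, pools, _ = fig3b
        ref = sk_inf_kt(params, pools).SK_inf
        for _ in range(10):
            perturbed = params.replace(
                lambda2=float(rng.uniform(0.01, 100)),
                lambda_m2=float(rng.uniform(0.01, 100)),
            )
            assert sk_inf_kt(perturbed, pools).SK_inf == ref

    def test_kt_asymptote_matches_large_kt_numeric(self, fig3b):
        params, pools, _ = fig3b
        asym = sk_inf_kt(params, pools)
        p = pools.replace(Kt=1e6 * pools.Pt)
        r_numeric = r_from_sk(solve_sk(params, p), params, p)
        assert r_numeric == pytest.approx(asym.R_inf, rel=1e-4)

    def test_st_limit_kinase_wins(self, fig3b):
        params, pools, _ = fig3b  # alpha = 1
        assert r_inf_st(params, pools.replace(Pt=1, Kt=2)).R_inf == 1.0
        assert r_inf_st(params, pools.replace(Pt=4, Kt=2)).R_inf == 0.0

    def test_st_limit_degenerate_boundary(self, fig3b):
        params, pools, _ = fig3b
        with pytest.raises(DegenerateBoundary):
            r_inf_st(params, pools.replace(Pt=2.0, Kt=2.0))

    def test_large_st_over_pt_gives_full_phosphorylation(self, fig3b):
        params, pools, _ = fig3b
        r = sk_inf_kt(params, pools.replace(St=1e8 * pools.Pt)).R_inf
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_large_alpha_gives_full_phosphorylation(self, fig3b):
        params, pools, _ = fig3b
        r = sk_inf_kt(params.replace(k2=1e8), pools).R_inf
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_large_lambda1_branches(self, fig3b):
        # strong phosphatase binding (lambda1 -> inf, so M1 -> 0):
        # Pt/alpha > St/(alpha+1): [SK] -> St/(alpha+1), R -> alpha/(alpha+1);
        # Pt/alpha < St/(alpha+1): [SK] -> Pt/alpha and the indeterminate
        # M1/(Pt - alpha[SK]) term tends to a finite value, giving
        # R -> 1 - Pt/(alpha St) (which approaches 1 only for St >> Pt/alpha)
        params, pools, _ = fig3b  # alpha = 1
        sequestered = pools.replace(Pt=100.0, St=10.0)  # 100 > 5
        r = sk_inf_kt(params.replace(lambda1=1e9), sequestered).R_inf
        assert r == pytest.approx(0.5, abs=1e-3)
        free = pools.replace(Pt=1.0, St=10.0)  # 1 < 5
        r = sk_inf_kt(params.replace(lambda1=1e9), free).R_inf
        assert r == pytest.approx(1.0 - 1.0 / 10.0, abs=1e-3)
        # and the full-phosphorylation limit is recovered at large St/Pt
        wide = pools.replace(Pt=1.0, St=1e4)
        r = sk_inf_kt(params.replace(lambda1=1e9), wide).R_inf
        assert r == pytest.approx(1.0, abs=1e-3)


class TestInverses:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.01, 0.95), st.integers(0, 10_000))
    def test_sk_r_round_trip(self, frac, seed):
        params, pools = random_basic_set(np.random.default_rng(seed))
        r_target = frac * sk_inf_kt(params, pools).R_inf
        sk = sk_from_r(r_target, params, pools)
        assert r_from_sk(sk, params, pools) == pytest.approx(r_target, rel=1e-10)

    def test_kt_sk_round_trip_random(self, rng):
        for _ in range(50):
            params, pools = random_basic_set(rng)
            sk = solve_sk(params, pools)
            if sk <= 0:
                continue
            kt = kt_from_sk(sk, params, pools)
            assert kt == pytest.approx(pools.Kt, rel=1e-9)
            sk_back = solve_sk(params, pools.replace(Kt=kt))
            assert sk_back == pytest.approx(sk, rel=1e-9)

    def test_kt_diverges_at_asymptote(self, fig3b):
        params, pools, _ = fig3b
        sk_inf = sk_inf_kt(params, pools).SK_inf
        near = kt_from_sk(sk_inf * (1 - 1e-7), params, pools)
        far = kt_from_sk(sk_inf * (1 - 1e-4), params, pools)
        assert near > 100 * far  # Kt ~ 1/(SK_inf - sk)
        with pytest.raises(DomainError):
            kt_from_sk(sk_inf * (1 + 1e-3), params, pools)  # beyond the plateau


class TestHillNumbers:
    def test_fig5a_basic_is_hyperbolic(self):
        params, pools, _ = fixture("fig5a_basic")
        assert hill_number_analytic(params, pools).nH == pytest.approx(1.0, abs=0.05)

    def test_fig6b_basic_is_hyperbolic(self):
        params, pools, _ = fixture("fig6b")
        assert hill_number_analytic(params, pools).nH == pytest.approx(1.0, abs=0.05)

    def test_fig6a_ultrasensitive(self, fig6a):
        params, pools, _ = fig6a
        res = hill_number_analytic(params, pools)
        assert res.nH > 2.0
        assert res.Kt10 < res.Kt90

    def test_response_coefficient_agrees_with_hill_fit(self, fig6a):
        # the two nH estimators agree within 5% on the printed sets
        for name in ("fig5a_basic", "fig6a", "fig6b"):
            params, pools, _ = fixture(name)
            rc = hill_number_analytic(params, pools).nH
            fit = hill_number_fit(params, pools)
            assert rc == pytest.approx(fit, rel=0.05)

    def test_monotone_in_kt(self, rng):
        # dR/dKt > 0: finite differences on random parameter sets
        for _ in range(30):
            params, pools = random_basic_set(rng)
            kts = np.logspace(-2, 3, 40) * max(pools.Pt, 0.1)
            R = [
                r_from_sk(solve_sk(params, pools.replace(Kt=k)), params,
                          pools.replace(Kt=k))
                for k in kts
            ]
            assert np.all(np.diff(R) > -1e-12)
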
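# Methods

## The model

A phosphorylation–dephosphorylation cycle (PDC) interconverts a substrate
between its unphosphorylated form S and phosphorylated form Sp:

    Sp + P  <->[lambda1, lambda_m1]  SpP  ->[k1]  S + P      (phosphatase)
    S  + K  <->[lambda2, lambda_m2]  SK   ->[k2]  Sp + K     (kinase)

All species are treated with mass-action kinetics; association rates are in
uM^-1 s^-1, dissociation and catalytic rates in s^-1, concentrations in uM.
The three totals Kt, Pt, St are conserved.  The response variable throughout
is the *total* phosphorylated fraction R = ([Sp] + [SpP])/St (every species
that carries the phosphate counts), the quantity a downstream effector that
recognizes the phosphorylated epitope would see.

The extended model adds reversible association of the two converter enzymes
into a single complex PK (dissociation constant omega = kappa_m1/kappa1) and
two optional catalytic arms of that complex:

    Sp + PK <->[lambda3, lambda_m3]  SpPK ->[k3]  S + PK     (complex phosphatase)
    S  + PK <->[lambda4, lambda_m4]  SPK  ->[k4]  Sp + PK    (complex kinase)

Five variants are distinguished by which arms are live: `basic` (no complex),
`complex_inactive`, `complex_P_active`, `complex_K_active`,
`complex_both_active`.  An "inactive" arm has zero association and zero
catalysis; its dissociation rate is retained so that complexes formed before
an activity switch can drain instead of teleporting their mass.  Whether a
catalytically dead enzyme inside the complex can still bind substrate
non-productively is not constrained by the parameterizations we reproduce;
we model no such binding.

Both ternary complexes SpPK and SPK contain *both* enzymes, so the conserved
totals are Pt = [P] + [SpP] + [SpPK] + [SPK] + [PK] and
Kt = [K] + [SK] + [SpPK] + [SPK] + [PK]; the right-hand sides preserve these
identically (asserted to 1e-8 relative along every integration).

## Exact steady state of the basic cycle

At a fixed point the two Michaelis relations M1[SpP] = [Sp][P],
M2[SK] = [S][K] (Mi = (lambda_mi + ki)/lambdai), the flux balance
[SpP] = alpha[SK] (alpha = k2/k1), and conservation collapse the basic cycle
to a monic cubic in [SK]:

    [SK]^3 + (-Kt + v1)[SK]^2 + (u1 Kt + v2)[SK] + u2 Kt = 0,
    u1 = Pt/alpha + (M1+St)/(alpha+1),      u2 = -Pt St/(alpha(alpha+1)),
    v1 = -Pt/alpha - (M1+M2+St)/(alpha+1),  v2 = Pt(M2+St)/(alpha(alpha+1)).

These coefficients were derived symbolically (sympy) and frozen; every root
the package returns is cross-checked in the test suite against full-ODE
relaxation.  The admissible root satisfies 0 <= [SK] <= min(Kt, St) and
alpha[SK] < Pt and is unique on all sampled parameter sets; root finding
uses the companion-matrix method plus a bracketed Brent polish because the
closed forms cancel catastrophically at the extreme pool ratios
(St/Pt up to 1e4) the sweeps visit.  If floating-point noise ever yields two
near-admissible candidates the one with the smaller cubic residual is taken
and a warning emitted.

The phosphorylated fraction follows as
R = (alpha[SK]/St)(M1/(Pt - alpha[SK]) + 1) and is provably <= 1 and
strictly increasing in Kt.  As Kt -> infinity the cubic degenerates to
[SK]^2 - u1[SK] - u2 = 0 whose minus branch gives the plateau SK_inf and
R_inf; we evaluate it in the rationalized form -2 u2/(u1 + sqrt(u1^2+4u2)),
since the textbook form loses half the mantissa when |u2| << u1^2.  R_inf
can sit well below 1 (partial asymptotic phosphorylation): the phosphatase
sequesters substrate when St/Pt is small, alpha is small, or lambda1/lambda2
is large.

Limiting cases implemented and tested: R_inf -> 1 as St/Pt -> infinity or
alpha -> infinity; as lambda1 -> infinity (so M1 -> 0), R_inf ->
alpha/(alpha+1) when Pt/alpha > St/(alpha+1), and otherwise
R_inf -> 1 - Pt/(alpha St).  The last expression comes from expanding the
indeterminate product M1/(Pt - alpha[SK]) as both factors vanish; it
approaches full phosphorylation only in the additional limit
St >> Pt/alpha.  The large-St limit of R is a step: 1 when Pt/alpha < Kt
(maximal kinase velocity wins), 0 when Pt/alpha > Kt, with the boundary
Pt/alpha = Kt reported as degenerate — the bell-shaped substrate response
lives just above that line.

## Hill numbers

Ultrasensitivity is quantified with the response coefficient relative to the
curve's own plateau: R10 = 0.1 R_inf and R90 = 0.9 R_inf are mapped to
[SK] by inverting R([SK]) (minus branch of the quadratic), then to Kt by the
exact relation Kt = ([SK]^3 + v1[SK]^2 + v2[SK])/([SK]^2 - u1[SK] - u2)
(the cubic is linear in Kt), and nH = log 81 / log(Kt90/Kt10).  Taking the
levels relative to R_inf rather than to 1 keeps nH meaningful under partial
asymptotic phosphorylation.  A second estimator fits R_inf/(1 + (K/Kt)^n)
to the exact curve with the plateau fixed; the two agree within 5% on all
shipped parameter sets (e.g. 2.06 vs 2.15 on the `fig6a` basic subset — the
ultrasensitive value quoted for that panel matches the fit estimator).
For extended variants, where no closed form exists, the same
response-coefficient construction is applied to the numerically computed
curve with the plateau taken from the curve's large-Kt end (or, for the
phosphatase-active variant, from the substitution asymptote below).

An important corollary of the exact solution, exercised in the tests: a low
plateau caps ultrasensitivity.  Wherever R_inf < 0.2 on the baseline scans
the Hill number stays below 5, while nH of 13–43 occurs only near-complete
asymptotic phosphorylation (R_inf ~ 0.9–0.99, the zero-order regime).

## Numerical steady states and transients

The extended model's fixed points are only defined implicitly, so they are
computed by stiff relaxation (LSODA, falling back to BDF) in expanding time
windows followed by a Newton polish on the conservation-reduced coordinate
set.  Coordinates whose dynamics are identically zero (an arm with all three
rates zero freezes its ternary complex) are excluded from the polish —
including them leaves a singular direction along which the root finder
drifts mass unphysically.  The converged residual must satisfy
max|dy/dt| < 1e-10 uM/s scaled by max(1, Kt, Pt, St); the scaling reflects
that for ~1e5 uM pools the mass-action fluxes are so large that double
precision cannot represent a smaller imbalance.  Non-convergence raises; no
partial results are returned.  Uniqueness of extended-model fixed points is
not proven; the suite checks that five random feasible initial conditions
reach the same state on the shipped sets and would flag multistability.

Trajectories use LSODA with rtol 1e-10, atol 1e-12 uM (rates span
0.01–500 s^-1 across the shipped sets) and keep dense output for peak and
event detection.  The default initial condition is the unphosphorylated
start ([S] = St, enzymes free): fixed points are observed unique, so the
choice only affects transients, and it matches the membrane-recruitment
narrative of the transient scenarios.

Transient time is the smallest t after which |R(t) - R_ss| stays within a
tolerance (default 1e-4, halving it moves the times by < 20%); on the
shipped transient-time sweep the extended model's times track the basic
model's within a factor of two and both peak at the ultrasensitive
threshold, because enzyme-pair association is fast compared with substrate
turnover there.

## tQSSA reduction

For the phosphatase-active variant the total quasi-steady-state
approximation uses slow variables A = [Sp] + [SpP] (phosphorylated substrate
outside the enzyme-pair complex) and X = [SpPK] + [PK] (total enzyme pair).
Given (A, X) the three fast-complex relations decouple exactly: C1 = [SpP]
solves a standalone quadratic (minus branch, continuous with the
zero-substrate limit), C2 = [SpPK] is then linear, C3 = [SK] another
quadratic — a single pass, no iteration, residuals < 1e-10 uM^2.  The slow
system is dX/dt = kappa1([P][K]) - kappa_m1(X - C2),
dA/dt = -k1 C1 + k2 C3 - k3 C2.  Because the -k3 C2 sink encodes complex
*phosphatase* activity, the module refuses kinase-active variants rather
than extrapolating an unvalidated reduction.

Steady states of the reduced system are continued along the Kt sweep
(previous solution as the next starting point, with fresh-start fallbacks).
When kappa1 = 0 the X equation is identically zero and the 2-D root problem
is singular; the sweep then solves the remaining scalar balance in A by
bisection.  In that limit — and in fact at any true fixed point — the
fast-complex relations are exact, so reduced-model steady states coincide
with the full model's to solver precision; the approximation content of
tQSSA is in the transient dynamics.  The naive free-substrate QSSA
(Michaelis–Menten flux balance with enzyme partitioning but no substrate
sequestration) is provided as the weaker reference: it misses the
bell-shaped response entirely, which is how the bell is diagnosed as an
enzyme–substrate-complex effect.

## Bell-shaped responses

Two non-monotonic regimes are analyzed.  (i) Basic cycle, substrate sweep:
just above the balance line Pt/Kt = alpha the curve R(St) rises above its
small-St baseline R0 before collapsing to its large-St limit 0.  R0 is
evaluated analytically at St = 1e-6 min(Pt, M1) (stable to < 1e-4 under
halving).  The bell metric is RmaxSt/R0 with the maximum refined by
three-point parabolic interpolation in log St; a maximum on the sweep
boundary is flagged and never reported as a bell, and threshold masks in
parameter scans count only interior peaks above 1.05 — monotone curves
rising from a sequestration-suppressed R0 toward 1 would otherwise
masquerade as bells below the balance line.  (ii) Phosphatase-active
extended model, kinase sweep: free kinase first wins (R rises toward the
basic-cycle plateau), then accumulating PK — a stronger phosphatase —
pulls R down to a lower plateau.  That lower plateau has a closed form: at
saturating kinase essentially no free phosphatase remains, so the system is
a basic cycle whose phosphatase arm is the complex arm, and substituting
(lambda3, lambda_m3, k3) for (lambda1, lambda_m1, k1) in the basic
asymptote gives R_inf of the extended model (checked against full ODE at
Kt = 1e5 Pt to 1e-3; convergence is O(1/Kt)).  Robustness scans vary omega
through kappa_m1, M3 through lambda3, and Pt, exactly as the shipped
parameter sets prescribe.

## Transient phosphoinositide scenarios

Two mechanisms for a pulse of phosphorylated lipid on a maturing endosome:

* **Linear kinase recruitment** (phosphatase-active complex, fixed Pt): a
  constant source term on free kinase makes Kt(t) = Kt(0) + rate*t exactly
  (newly recruited enzyme arrives unbound; substrate and phosphatase totals
  stay conserved to 1e-8).  As Kt(t) crosses the bell-shaped dose-response,
  R rises, peaks, and decays to the nonzero substituted-arm asymptote with
  no trigger required.  The shipped parameter set (rate 0.0003 uM/s,
  Pt = 0.2, St = 300, k3 = 500) pins the steady-state bell maximum at
  Kt ~ 4 uM, so the quasi-statically tracked transient peaks at
  ~1.2e4 s (= argmax/rate); the published account of this panel quotes a
  ~300 s peak, which would require a ~40-fold faster recruitment — the
  acceptance script reports the honestly computed time.
* **Triggered activity switch** (fixed pools): the complex acts as a kinase
  until the switch time, then as a phosphatase.  Integration restarts
  exactly at the switch; the deactivated arm's association and catalysis
  are zeroed while its bound complexes drain through the retained
  dissociation rate (default) or are instantly converted to S + PK behind a
  flag — both fates conserve mass and agree at long times.  R peaks at the
  switch by construction and collapses after it.

Peak times are refined by golden-section search on the dense solver output;
a maximum at the window end is flagged as a running maximum, not a peak.

## Random parameter sampling

Property tests draw basic-cycle rates log-uniformly from 0.1–10 (uM^-1 s^-1
or s^-1) and pools from 0.1–100 uM (Kt from 0.01 uM) — the order-of-
magnitude envelope of the shipped parameter sets, chosen once to keep the
stiffness budget of the ODE cross-checks moderate.  Seeds are fixed;
`sample_params` is reproducible given a seed.

## What the shipped parameter sets do and do not show

The fixtures are the printed parameterizations of the figure panels the
package reproduces (`fig3a` … `fig9_recruitment`); they define desk-scale,
deterministic computations with no external data.  Passing tests demonstrate
internal consistency (analytic vs ODE vs reduced routes agree) and
reproduction of the quoted metrics at those exact parameter values; they do
not calibrate the models to any measured phosphoinositide kinetics, and the
scenarios are mechanism demonstrations, not fits to endosome-maturation
time courses.  Known limitations: no stochastic kinetics, no spatial or
compartmental structure, no multi-lipid network coupling, and the tQSSA
reduction is deliberately restricted to the phosphatase-active variant.
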
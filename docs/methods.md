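# Methods

## Model

`tcrkp` implements a mass-action model of the first minutes of T-cell
receptor (TCR) signalling. A chain of N phosphorylation sites on the
TCR complex is phosphorylated sequentially while the ligand stays
bound; the phosphatase SHP-1 provides negative feedback. State
variables are the active SHP-1 concentration S, the agonist-bound
complexes C_0..C_N (index = number of phosphorylations) and,
optionally, antagonist-bound complexes D_0..D_N:

    dS/dt   = alpha (C_1 + D_1)(S_T - S) - beta S
    dC_0/dt = kappa (L_1 - Sigma_1)(R - Sigma_1 - Sigma_2)
              + (b + gamma S) C_1 - (phi + nu_1) C_0
    dC_j/dt = phi C_{j-1} + (b + gamma S) C_{j+1}
              - (phi + b + gamma S + nu_1) C_j        (1 <= j <= N-1)
    dC_N/dt = phi C_{N-1} - (b + gamma S + nu_1) C_N

with Sigma_1 = sum_j C_j, Sigma_2 = sum_j D_j, and the D-chain obtained
by substituting nu_2 for nu_1. Free ligand, receptor and inactive
phosphatase have been eliminated using the four conservation laws
(totals L_1, L_2, R, S_T). The activation readout is C_N (or
C_N + D_N), the maximally phosphorylated complex.

All quantities are in arbitrary concentration/time units; the model
fixes no absolute scale and the package performs no unit conversion.

Assumptions inherited from the model: mass-action kinetics, strictly
sequential (de)phosphorylation, a single shared binding rate kappa for
both ligands, activation of SHP-1 only by singly phosphorylated
complexes, spatially well-mixed concentrations, and a time scale short
enough that receptor internalization and downstream gene regulation
are ignorable.

## Steady-state enumeration

The bound-ligand pools close on themselves: Sigma_1 and Sigma_2 obey a
planar competitive system whose steady state (Sigma_1*, Sigma_2*) is
unique. Agonist-only, Sigma_1* solves the quadratic
kappa (L_1 - Sigma)(R - Sigma) = nu_1 Sigma in closed form; with an
antagonist, a scalar decreasing-vs-increasing equation in
Sigma_1* + Sigma_2* is solved by bracketed bisection (relative
tolerance 1e-12).

On the attractor, the chain equations with Sigma_1* fixed reduce to a
polynomial p(S) of degree N+1 in S. The package builds p by
elimination: the phosphatase balance gives
C_1 = beta S / (alpha (S_T - S)); the steady-state chain recurrences
give an unnormalized profile T_j(S) (a polynomial of degree N - j,
built downward from the fully phosphorylated end); substituting into
the remaining equation and clearing denominators yields

    p(S) = beta S [phi sum_j T_j - x T_2 + (phi + x + nu_1) T_1]
           - alpha phi Sigma_1* (S_T - S) T_1,       x = b + gamma S.

For N <= 3 the classical hand-derived quadratic/cubic/quartic
coefficient formulas are also implemented and the two routes must agree
to a relative 1e-9 after normalization, a guard against transcription
errors in the closed forms (two such slips in the commonly quoted
quartic — a stray gamma on the beta-part of a_1 and gamma vs gamma^2 in
a_3 — were found this way and corrected; the elimination route is
authoritative). An exact-arithmetic sympy elimination is kept as a
third route for N <= 5 and exercised in the tests.

p has a negative constant term and positive leading coefficient
(beta gamma^N for chain length N), so Descartes' rule of signs bounds
the number of positive roots; for N = 1 and N = 2 the sign pattern
forces exactly one, and for N = 3 one or three. Roots are computed
from the companion matrix, polished by Newton iteration, filtered for
positivity (threshold 1e-14 times the root scale) and merged when
closer than 1e-8 times the root scale (reported as multiple). Each
root is back-substituted to (S, C_0..C_N); reconstructions with any
non-positive coordinate are rejected as spurious, and surviving states
must satisfy |rhs| < 1e-8 * scale. States are reported sorted by
ascending S.

The scaled family S_T = s̄_T / eps, nu_1 = n̄u_1 eps^4 (with kappa
rescaled so nu_1/kappa, hence Sigma_1*, is fixed, and b = 0) realizes
three positive roots for small eps: p(1) < 0 while p(eps^2) > 0.

## Chain parametrization and the response function

At fixed S the steady-state chain is a constant-coefficient linear
difference equation, so C_j = a_+ r_+^j + a_- r_-^j where r_- < 1 < r_+
solve phi + x r^2 - (phi + x + nu_1) r = 0. The roots are evaluated in
a cancellation-free form (r_+ from the positive branch, r_- = phi /
(x r_+)); the boundary factors phi - (x + nu_1) r_± are evaluated as
x r_±^2 (r_∓ - 1), which the characteristic equation makes exact and
which avoids severe cancellation when nu_1 << x. The coefficients a_±
follow from the two chain-end conditions and are positive.

This yields a second, independent steady-state solver: substitute
C_1(S) into the phosphatase balance and locate all roots of
alpha C_1(S) (S_T - S) = beta S by a dense log-spaced scan over
(0, S_T) (default 1e4 points, vectorized) plus bisection. A dense scan
is used rather than a single Newton start because up to three solutions
coexist and none may be missed. The polynomial and parametrization
routes are required to agree to 1e-8 in the tests; the same scan solves
the antagonist case, where both chains share S and the balance uses
C_1(S) + D_1(S).

The response function F(log L_1, nu_1) = log C_N* is evaluated by
enumerating steady states per grid point; it is multi-valued where the
system is multistable, and branches are connected across the grid by
nearest-neighbour matching in S. Grid intervals where the branch count
changes are recorded as fold brackets and refined by bisection on the
root count (no pseudo-arclength continuation: grids at desk scale
resolve the folds to ~1e-12 relative width).

Two asymptotic regimes are implemented:

- Small dose (L_1 << R, S -> 0): C_N ~ {r_-^N (1 - r_-/r_+)/(1 -
  (r_-/r_+)^{N+1}) * kappa R/(kappa R + nu_1)} L_1 (1 + q L_1/R) with
  -1/4 < q < 0. The q = 0 leading term is reported together with the
  bracketed interval (the constant inside the bracket is only bounded,
  not known, so an interval is the honest output). Log-log slope one.
- Intermediate regime (kappa R >= 1, L_1/R <= 1, phosphatase well away
  from 0 and S_T): C_N ~ (phi beta/(alpha gamma S_T))^{N/2}
  ((kappa R + nu_1)/(kappa R))^{N/2-1} L_1^{1-N/2}. For N > 2 this
  *decreases* with dose and *increases* with nu_1 — the mechanism
  behind the non-monotone dose-response and the optimal dissociation
  time. The expansion parameters eta = (phi + nu_1)/(b + gamma S),
  eta' = max(eta, b/(gamma S)) and eta'' = max(eta', L_1/R) are
  computed from the self-consistent estimate
  S = sqrt(phi kappa R S_T L_1 / (C_* gamma (kappa R + nu_1))),
  C_* = beta/alpha, and a warning flag is raised when eta'' >= 0.3.
  Note that scaling S_T up while scaling L_1 down leaves S — and hence
  eta — unchanged; the approximation error genuinely shrinks when S_T
  grows at fixed dose, and the tests check exactly that.

With an antagonist the same leading-order expression holds for
C_N + D_N after replacing kappa R L_1/(kappa R + nu_1) by
kappa R L_1/(kappa R + nu_1) + kappa R L_2/(kappa R + nu_2); for N = 3
it is decreasing in L_2 at fixed L_1, which the exact solver confirms
in sign at the validated deep-regime point used in the tests
(S_T = 6e9 variant of the dose-response example). More antagonist
then means less response although receptor competition is negligible
— the suppression travels through shared SHP-1.

## Stability and dynamics

The Jacobian of the full system is assembled analytically (dimension
1 + (N+1), plus another N+1 when the antagonist chain is active) and
verified against central finite differences. Classification uses the
eigenvalue signs with a marginality tolerance of 1e-8 relative to the
spectral radius, so it is scale-free: any eigenvalue within tolerance
of the imaginary axis yields the label "marginal", never a silent
"stable". The unstable-manifold dimension counts eigenvalues with real
part above +tolerance. "stable-focus" vs "stable-node" is decided by
whether the dominant (rightmost) pair is complex.

For N = 1 the limiting (S, C_1) system has negative divergence, so
every orbit converges; damped oscillations occur where
alpha C_1 + beta = phi + b + gamma S + nu_1 holds at the steady state,
because there the discriminant of the 2x2 characteristic polynomial
reduces to -4 alpha gamma (S_T - S) C_1 < 0. The solver imposes this
balance self-consistently: an inner closed-form steady-state solve
given beta, an outer bisection on beta (default bracket 1e-8..1e4).
When the bracket does not straddle the balance on a parameter slice,
that is reported rather than forced. Whether *sustained* oscillations
exist anywhere in parameter space is open; the package only reports
eigenvalue structure and a trajectory diagnostic.

Time integration uses LSODA with the analytic Jacobian (rtol 1e-9,
atol 1e-12) — rate constants of interest span ten orders of magnitude,
so a stiff-capable method is required. With no explicit horizon the
orbit is extended in ten-fold windows until the scaled right-hand side
falls below 1e-10 or t = 1e6. Trajectories record the minimum
feasible-region margin at every step; persistence (margins bounded away
from zero) is checked on random interior starts in the tests. Basin
estimation integrates seeded random interior starts and matches
terminal states against the enumerated equilibria; unmatched or
non-convergent starts are counted separately, never silently assigned.
The damped-oscillation diagnostic requires at least two sign changes of
the observable's derivative with excursion amplitudes decaying toward
the limit (5% slack per step for sampling noise).

## Feasibility bookkeeping

A state's six slacks — S, S_T - S, L_1 - Sigma_1, L_2 - Sigma_2,
R - Sigma_1 - Sigma_2 and the smallest complex concentration — are
reported explicitly; classification interior/boundary/outside uses an
absolute tolerance of 1e-10. For agonist-only instances the inert
antagonist block is excluded from the margins. b = 0 (no basal
dephosphorylation) is accepted with a logged warning because the
three-steady-state construction uses it; alpha = 0 (no feedback) is
accepted as the kinetic proofreading limit, in which S decays to zero
and the chain decouples — its steady state lies on the S = 0 boundary
and is obtained from the chain parametrization at S = 0 rather than
from the polynomial (which assumes alpha > 0).

## Problem sizes and determinism

Everything here is desk-scale: quartic root finding, 2- to 9-dimen-
sional ODEs, and grids of 1e2..1e4 points. The test suite uses 100-
to 1000-draw randomized parameter sweeps (moderate log-uniform ranges,
fixed numpy seeds), multistart basins of 12-24 orbits and response
grids of 90-140 points; all randomness is seeded, and config-driven
runs write byte-identical CSVs on repetition.

## Known limitations

- The printed closed-form polynomial coefficients exist only for
  N <= 3; for larger N only the elimination and sympy routes apply,
  and no bound on the number of steady states is asserted for N > 3
  beyond Descartes' count (three is the most ever observed here).
- The intermediate-regime formulas are leading-order only; the package
  reports eta'' and flags regime violations but does not carry the
  O(eta'') constants.
- Boundary-layer cases (nu_1/x below ~1e-12, eps below ~1e-3 in the
  scaled family) push the quartic's roots toward multiplicity and the
  root-merging heuristic may report a merged pair.
- No stochastic (chemical master equation) simulation, no spatial
  effects, no downstream ERK cascade, and no fitting to experimental
  dose-response data.
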
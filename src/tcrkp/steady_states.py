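"""Enumeration of positive steady states via polynomial elimination.

At a steady state the total bound-agonist pool Sigma1 satisfies a scalar
equation with a unique solution Sigma1*, after which the chain equations
reduce (agonist-only) to a single polynomial of degree N+1 in the active
phosphatase level S.  Its positive roots, bounded in number by
Descartes' rule of signs, are back-substituted to full concentration
vectors.  For N <= 3 the polynomial coefficients are also available in
closed form and the two routes are cross-checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .model import ModelParams, State, rhs_full

logger = logging.getLogger(__name__)

__all__ = [
    "SigmaSolution",
    "SPolynomial",
    "SteadyState",
    "SpuriousRootError",
    "solve_sigma",
    "build_s_polynomial",
    "printed_coefficients",
    "elimination_coefficients",
    "symbolic_coefficients",
    "positive_roots",
    "backsubstitute",
    "enumerate_steady_states",
    "epsilon_family",
]


class SpuriousRootError(ValueError):
    """A polynomial root that does not yield a positive steady state."""


@dataclass(frozen=True)
class SigmaSolution:
    """Unique steady-state values of the bound-ligand pools."""

    sigma1: float
    sigma2: float
    residual1: float
    residual2: float

    @property
    def total(self) -> float:
        return self.sigma1 + self.sigma2


@dataclass
class SPolynomial:
    """Polynomial p(S) whose positive roots are the steady-state S values.

    ``coeffs`` is in ascending degree; the constant term is negative and
    the leading term positive, so Descartes' rule bounds the number of
    positive roots by the number of sign changes.
    """

    coeffs: np.ndarray
    provenance: str  # "printed-formula" | "eliminated"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, S):
        return np.polynomial.polynomial.polyval(S, self.coeffs)

    def derivative(self, S):
        dc = self.coeffs[1:] * np.arange(1, len(self.coeffs))
        return np.polynomial.polynomial.polyval(S, dc)

    @property
    def sign_changes(self) -> int:
        signs = np.sign(self.coeffs)
        signs = signs[signs != 0]
        return int(np.sum(signs[1:] != signs[:-1]))


@dataclass
class SteadyState:
    """A positive equilibrium of the full system."""

    state: State
    s_root: float
    sigma: SigmaSolution
    residual: float
    stability: object | None = None  # filled by the stability module

    @property
    def S(self) -> float:
        return self.state.S

    @property
    def C(self) -> np.ndarray:
        return self.state.C

    @property
    def CN(self) -> float:
        return float(self.state.C[-1])


def _stable_quadratic_roots(a: float, b: float, c: float) -> tuple[float, float]:
    """Roots of a x^2 + b x + c, avoiding cancellation; returns (small, large)."""
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("negative discriminant")
    q = -0.5 * (b + np.copysign(np.sqrt(disc), b))
    r1, r2 = q / a, (c / q if q != 0 else 0.0)
    return (r1, r2) if r1 <= r2 else (r2, r1)


def solve_sigma(params: ModelParams, rtol: float = 1e-12) -> SigmaSolution:
    """Solve for the unique steady state of the bound-ligand pools.

    Agonist-only instances use the closed-form quadratic
    kappa(L1 - Sigma)(R - Sigma) = nu1 Sigma, taking the root in
    [0, min(L1, R)].  With an antagonist, the scalar equation for
    Sigma1 + Sigma2 is decreasing-vs-increasing on its bracket and is
    solved by bracketed root finding.
    """
    p = params
    if p.L1 == 0 and p.L2 == 0:
        raise ValueError("no ligand present (L1 = L2 = 0)")
    if p.agonist_only:
        # kappa*Sigma^2 - (kappa*(L1+R) + nu1)*Sigma + kappa*L1*R = 0
        s1, _ = _stable_quadratic_roots(
            p.kappa, -(p.kappa * (p.L1 + p.R) + p.nu1), p.kappa * p.L1 * p.R)
        sigma1, sigma2 = float(s1), 0.0
    else:
        def gap(total: float) -> float:
            fr = p.R - total
            rhs = (p.kappa * p.L1 * p.nu1 / (p.kappa * fr + p.nu1)
                   + p.kappa * p.L2 * p.nu2 / (p.kappa * fr + p.nu2))
            return p.kappa * (p.L1 + p.L2 - total) - rhs

        hi = min(p.L1 + p.L2, p.R)
        total = brentq(gap, 0.0, hi, xtol=1e-300, rtol=max(rtol, 1e-14))
        fr = p.R - total
        sigma1 = p.kappa * p.L1 * fr / (p.kappa * fr + p.nu1)
        sigma2 = p.kappa * p.L2 * fr / (p.kappa * fr + p.nu2)
    fr = p.R - sigma1 - sigma2
    res1 = p.kappa * (p.L1 - sigma1) * fr - p.nu1 * sigma1
    res2 = p.kappa * (p.L2 - sigma2) * fr - p.nu2 * sigma2
    return SigmaSolution(sigma1, sigma2, res1, res2)


# ---------------------------------------------------------------------------
# the degree-(N+1) polynomial in S (agonist-only)

def _tail_polynomials(params: ModelParams) -> dict[int, Polynomial]:
    """Unnormalized steady-state chain profile T_j(S), C_j proportional to T_j.

    Built downward from the fully phosphorylated end: T_N = phi^(N-1),
    T_{N-1} = phi^(N-2) (b + gamma S + nu1), then
    phi T_{j-1} = (phi + x + nu1) T_j - x T_{j+1} with x = b + gamma S.
    Each T_j is a polynomial in S of degree N - j.
    """
    p = params
    N = p.N
    x = Polynomial([p.b + p.nu1, p.gamma])  # x + nu1
    xb = Polynomial([p.b, p.gamma])         # x
    T = {N: Polynomial([p.phi ** (N - 1)])}
    if N >= 2:
        T[N - 1] = p.phi ** (N - 2) * x
    for j in range(N - 1, 1, -1):
        T[j - 1] = ((Polynomial([p.phi]) + x) * T[j] - xb * T[j + 1]) / p.phi
    return T


def elimination_coefficients(params: ModelParams, sigma: SigmaSolution
                             ) -> np.ndarray:
    """Ascending coefficients of p(S) by eliminating the chain variables.

    Substituting C1 = beta S / (alpha (ST - S)) from the phosphatase
    balance and the chain profile T_j into the remaining C1 equation and
    clearing denominators yields

        p(S) = beta S [phi sum_j T_j - x T_2 + (phi + x + nu1) T_1]
               - alpha phi Sigma* (ST - S) T_1.
    """
    p = params
    sig = sigma.sigma1
    S = Polynomial([0.0, 1.0])
    if p.N == 1:
        poly = (p.beta * S * Polynomial([p.phi + p.b + p.nu1, p.gamma])
                - p.alpha * p.phi * sig * (p.ST - S))
    else:
        T = _tail_polynomials(p)
        x = Polynomial([p.b, p.gamma])
        bracket = (p.phi * sum(T[j] for j in range(1, p.N + 1))
                   - x * T[2]
                   + (Polynomial([p.phi + p.nu1]) + x) * T[1])
        poly = p.beta * S * bracket - p.alpha * p.phi * sig * (p.ST - S) * T[1]
    c = poly.coef
    # pad in case of exact cancellation of the leading coefficient
    if len(c) < p.N + 2:
        c = np.pad(c, (0, p.N + 2 - len(c)))
    return np.asarray(c, dtype=float)


def printed_coefficients(params: ModelParams, sigma: SigmaSolution
                         ) -> np.ndarray:
    """Closed-form coefficients for N <= 3 (ascending degree).

    These are the hand-derived quadratic/cubic/quartic formulas; two
    transcription slips in the commonly quoted quartic (a stray gamma on
    the beta-term of a1, gamma vs gamma^2 in a3) are corrected here, as
    fixed by the elimination route.
    """
    p = params
    al, be, ga, ph, b, nu, ST = (p.alpha, p.beta, p.gamma, p.phi, p.b,
                                 p.nu1, p.ST)
    Sig = sigma.sigma1
    if p.N == 1:
        return np.array([
            -al * ph * Sig * ST,
            be * (ph + b + nu) + al * ph * Sig,
            be * ga,
        ])
    if p.N == 2:
        return np.array([
            -al * ST * (b + nu) * ph * Sig,
            (be * (b * (ph + b + nu) + nu * (2 * ph + b + nu) + ph ** 2)
             + al * (b + nu) * ph * Sig - al * ga * ST * ph * Sig),
            be * ga * (ph + 2 * b + 2 * nu) + al * ga * ph * Sig,
            be * ga ** 2,
        ])
    if p.N == 3:
        bn = b + nu
        return np.array([
            -(bn ** 2 + ph * nu) * al * ph * Sig * ST,
            (be * (bn ** 3 + ph * bn * (b + 3 * nu)
                   + ph ** 2 * (b + 3 * nu) + ph ** 3)
             + (bn ** 2 + nu * ph) * al * ph * Sig
             - 2 * bn * al * ga * ph * Sig * ST),
            (ga * be * (3 * b ** 2 + 6 * b * nu + 2 * b * ph
                        + 3 * nu ** 2 + 4 * nu * ph + ph ** 2)
             + 2 * bn * al * ga * ph * Sig - ga ** 2 * al * ph * Sig * ST),
            be * ga ** 2 * (3 * bn + ph) + ga ** 2 * al * ph * Sig,
            be * ga ** 3,
        ])
    raise ValueError("closed-form coefficients only available for N <= 3")


def symbolic_coefficients(params: ModelParams, sigma: SigmaSolution
                          ) -> np.ndarray:
    """Exact-arithmetic elimination via sympy (cross-check route, N <= 5)."""
    import sympy as sp

    p = params
    if p.N > 5:
        raise ValueError("symbolic route limited to N <= 5")
    S = sp.Symbol("S")
    vals = {k: sp.Rational(str(v)) for k, v in
            dict(al=p.alpha, be=p.beta, ga=p.gamma, ph=p.phi, b=p.b,
                 nu=p.nu1, ST=p.ST, Sig=sigma.sigma1).items()}
    al, be, ga, ph, b, nu, ST, Sig = (vals[k] for k in
                                      ("al", "be", "ga", "ph", "b", "nu",
                                       "ST", "Sig"))
    x = b + ga * S
    N = p.N
    if N == 1:
        poly = be * S * (ph + x + nu) - al * ph * Sig * (ST - S)
    else:
        T = {N: ph ** (N - 1)}
        if N >= 2:
            T[N - 1] = ph ** (N - 2) * (x + nu)
        for j in range(N - 1, 1, -1):
            T[j - 1] = sp.expand(((ph + x + nu) * T[j] - x * T[j + 1]) / ph)
        bracket = (ph * sum(T[j] for j in range(1, N + 1))
                   - x * T[2] + (ph + x + nu) * T[1])
        poly = be * S * bracket - al * ph * Sig * (ST - S) * T[1]
    coeffs = sp.Poly(sp.expand(poly), S).all_coeffs()[::-1]
    out = np.zeros(N + 2)
    out[:len(coeffs)] = [float(c) for c in coeffs]
    return out


def build_s_polynomial(params: ModelParams, sigma: SigmaSolution | None = None,
                       rtol: float = 1e-9) -> SPolynomial:
    """Degree-(N+1) polynomial in S whose positive roots give steady states.

    For N <= 3 the closed-form and elimination coefficients must agree
    to relative tolerance ``rtol`` (after normalizing the leading
    coefficient); disagreement raises, guarding against transcription
    errors in the closed forms.
    """
    p = params
    if not p.agonist_only:
        raise ValueError("the S-polynomial requires an agonist-only instance")
    if sigma is None:
        sigma = solve_sigma(p)
    elim = elimination_coefficients(p, sigma)
    if p.N <= 3:
        printed = printed_coefficients(p, sigma)
        a = elim / elim[-1]
        bcoef = printed / printed[-1]
        scale = np.maximum(np.abs(a), np.abs(bcoef)).max()
        if np.max(np.abs(a - bcoef)) > rtol * scale:
            raise RuntimeError(
                "printed-formula and elimination coefficients disagree: "
                f"{printed} vs {elim}")
        return SPolynomial(printed, "printed-formula")
    return SPolynomial(elim, "eliminated")


def positive_roots(poly: SPolynomial, polish_tol: float = 1e-12,
                   merge_rtol: float = 1e-8,
                   return_multiplicities: bool = False):
    """Positive real roots of the S-polynomial, sorted ascending.

    Roots come from the companion-matrix eigenvalues of the polynomial
    and are polished by Newton iteration.  Nearly coincident roots
    (closer than ``merge_rtol`` times the root scale) are merged and
    reported with multiplicity.
    """
    coeffs = poly.coeffs
    if coeffs[-1] == 0:
        raise ValueError("leading coefficient is zero")
    roots = Polynomial(coeffs).roots()
    scale = max(np.abs(roots).max(), 1e-300)
    real = roots[np.abs(roots.imag) < 1e-8 * scale].real
    pos = real[real > 1e-14 * scale]
    polished = []
    for r in pos:
        z = r
        for _ in range(50):
            f, df = poly(z), poly.derivative(z)
            if df == 0:
                break
            step = f / df
            z -= step
            if abs(step) < polish_tol * max(abs(z), scale * 1e-3):
                break
        if z > 0:
            polished.append(z)
    polished.sort()
    merged, mult = [], []
    for z in polished:
        if merged and abs(z - merged[-1]) < merge_rtol * scale:
            mult[-1] += 1
            logger.warning("near-multiple root at S=%.6g merged", z)
        else:
            merged.append(z)
            mult.append(1)
    if len(merged) > poly.sign_changes:
        raise RuntimeError("more positive roots than Descartes sign changes")
    roots_arr = np.array(merged)
    if return_multiplicities:
        return roots_arr, np.array(mult)
    return roots_arr


def _chain_from_s(params: ModelParams, sigma1: float, s_root: float
                  ) -> np.ndarray:
    """C_0..C_N at a steady state given S, by successive back-substitution."""
    p = params
    x = p.b + p.gamma * s_root
    C1 = p.beta * s_root / (p.alpha * (p.ST - s_root))
    C = np.empty(p.N + 1)
    C[1] = C1
    if p.N >= 2:
        # downward continued-fraction for the ratios rho_j = C_j / C_{j-1}
        rho = np.empty(p.N + 1)
        rho[p.N] = p.phi / (x + p.nu1)
        for j in range(p.N - 1, 1, -1):
            rho[j] = p.phi / (p.phi + x + p.nu1 - x * rho[j + 1])
        for j in range(2, p.N + 1):
            C[j] = C[j - 1] * rho[j]
    C[0] = sigma1 - C[1:].sum()
    return C


def backsubstitute(params: ModelParams, sigma: SigmaSolution, s_root: float,
                   residual_rtol: float = 1e-8) -> SteadyState:
    """Reconstruct the full steady state from a positive root S of p.

    C1 comes from the phosphatase balance C1 = beta S / (alpha (ST - S)),
    the higher C_j from the steady-state chain recurrences and
    C0 = Sigma* - sum_{j>=1} C_j.  Roots whose reconstruction has any
    non-positive coordinate are rejected as spurious.
    """
    p = params
    if p.alpha == 0:
        raise ValueError("back-substitution requires alpha > 0; in the "
                         "kinetic proofreading limit S = 0 and the chain "
                         "profile follows from the parametrization at S = 0")
    if not (0.0 < s_root < p.ST):
        raise SpuriousRootError(f"S root {s_root} outside (0, ST)")
    # polish the root first so that rounded inputs reconstruct cleanly
    poly = build_s_polynomial(p, sigma)
    z = float(s_root)
    for _ in range(50):
        df = poly.derivative(z)
        if df == 0:
            break
        step = poly(z) / df
        z -= step
        if abs(step) < 1e-14 * max(abs(z), 1e-300):
            break
    if 0.0 < z < p.ST and abs(z - s_root) < 0.05 * max(abs(s_root), 1e-300):
        s_root = z
    C = _chain_from_s(p, sigma.sigma1, s_root)
    if np.any(C <= 0):
        raise SpuriousRootError(
            f"root S={s_root:.6g} gives non-positive chain coordinates")
    state = State(s_root, C, np.zeros(p.N + 1))
    deriv = rhs_full(p, state)
    scale = max(1.0, float(np.abs(state.to_vector(False)).max()))
    residual = float(np.abs(deriv.to_vector(False)).max())
    if residual > residual_rtol * scale:
        raise SpuriousRootError(
            f"steady-state residual {residual:.3g} too large at S={s_root}")
    return SteadyState(state, float(s_root), sigma, residual)


def enumerate_steady_states(params: ModelParams) -> list[SteadyState]:
    """All positive steady states of an agonist-only instance, sorted by S.

    Exactly one state exists for N = 1 and N = 2; for N = 3 there are
    between one and three.  An antagonist instance is delegated to the
    coupled fixed-point solver in :mod:`tcrkp.response`.
    """
    p = params
    if p.alpha == 0:
        raise ValueError("alpha = 0 has its steady state on the S = 0 "
                         "boundary; use the chain parametrization at S = 0")
    if not p.agonist_only:
        from .response import antagonist_steady_state
        return antagonist_steady_state(p)
    sigma = solve_sigma(p)
    poly = build_s_polynomial(p, sigma)
    states = []
    for r in positive_roots(poly):
        try:
            states.append(backsubstitute(p, sigma, float(r)))
        except SpuriousRootError as exc:
            logger.info("rejected root: %s", exc)
    if not states:
        raise RuntimeError("no positive steady state found; existence is "
                           "guaranteed, so this indicates a numerical failure")
    if p.N <= 2 and len(states) != 1:
        raise RuntimeError(
            f"N={p.N} must have a unique steady state, found {len(states)}")
    states.sort(key=lambda s: s.S)
    return states


def epsilon_family(epsilon: float, sbar_T: float, nubar_1: float,
                   base: ModelParams) -> ModelParams:
    """Scaled parameter family exhibiting three steady states for small eps.

    Sets ST = sbar_T / eps and nu1 = nubar_1 eps^4, rescaling kappa so
    that nu1 / kappa (and hence Sigma*) is unchanged.  Requires b = 0;
    for sufficiently small eps the quartic satisfies p(1) < 0 and
    p(eps^2) > 0, forcing three positive roots.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if base.b != 0:
        raise ValueError("the scaling construction requires b = 0")
    nu1 = nubar_1 * epsilon ** 4
    kappa = base.kappa * nu1 / base.nu1
    return base.replace(ST=sbar_T / epsilon, nu1=nu1, kappa=kappa)
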
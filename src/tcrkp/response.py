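"""Response function of the activation readout C_N.

At a steady state the chain equations form a constant-coefficient
linear difference equation in j, so the profile decomposes as
C_j = a_+ r_+^j + a_- r_-^j with r_- < 1 < r_+ the roots of the
characteristic quadratic.  This parametrization underlies the
(possibly multi-valued) response function log C_N = F(log L1, nu1),
its small-L1 and intermediate-regime asymptotics, and the extension to
a competing antagonist ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.optimize import brentq

from .model import ModelParams, State, rhs_full
from .steady_states import (SteadyState, solve_sigma,
                            enumerate_steady_states)

logger = logging.getLogger(__name__)

__all__ = [
    "Parametrization",
    "ResponseCurve",
    "characteristic_roots",
    "solve_coefficients",
    "steady_states_by_parametrization",
    "response_function",
    "asymptotic_small_L1",
    "asymptotic_intermediate",
    "antagonist_steady_state",
    "antagonist_asymptotics",
]


@dataclass
class Parametrization:
    """Power-law decomposition C_j = a_+ r_+^j + a_- r_-^j at fixed S."""

    r_minus: float
    r_plus: float
    a_minus: float
    a_plus: float
    S: float
    A: float
    B: float
    C_star: float

    def profile(self, N: int) -> np.ndarray:
        j = np.arange(N + 1)
        return self.a_plus * self.r_plus ** j + self.a_minus * self.r_minus ** j


def _roots_raw(params: ModelParams, S, nu):
    """Vectorized characteristic roots (no validation)."""
    p = params
    x = p.b + p.gamma * np.asarray(S, dtype=float)
    q = p.phi + x + nu
    sq = np.sqrt(q * q - 4 * p.phi * x)
    r_plus = (q + sq) / (2 * x)
    r_minus = p.phi / (x * r_plus)    # product of roots = phi / x
    return x, r_minus, r_plus


def characteristic_roots(params: ModelParams, S: float,
                         nu: float | None = None) -> tuple[float, float]:
    """Roots r_- < 1 < r_+ of phi + x r^2 - (phi + x + nu) r = 0, x = b + gamma S.

    Computed in a cancellation-free form; ``nu`` defaults to the agonist
    dissociation rate (pass nu2 for the antagonist chain).
    """
    p = params
    nu = p.nu1 if nu is None else nu
    if p.b + p.gamma * S <= 0:
        raise ValueError("b + gamma*S must be positive")
    _, r_minus, r_plus = _roots_raw(p, S, nu)
    return float(r_minus), float(r_plus)


def solve_coefficients(params: ModelParams, S: float,
                       sigma_star: float | None = None,
                       nu: float | None = None) -> Parametrization:
    """Positive coefficients a_± of the steady-state chain profile.

    The ratio a_+/a_- follows from the boundary condition at the fully
    phosphorylated end; a_- from the condition at the unphosphorylated
    end, where the bracketed combination A - B (r_-/r_+)^(N-1) is
    positive.  The resulting profile satisfies sum_j C_j = sigma_star.
    """
    p = params
    nu_c = p.nu1 if nu is None else nu
    if sigma_star is None:
        sigma_star = solve_sigma(p).sigma1
    rm, rp, am, ap, A, B = _coefficients_raw(p, S, sigma_star, nu_c)
    c_star = p.beta / p.alpha if p.alpha > 0 else np.inf
    return Parametrization(float(rm), float(rp), float(am), float(ap),
                           S, float(A), float(B), C_star=c_star)


def _coefficients_raw(params: ModelParams, S, sigma_star: float, nu: float):
    """Vectorized (r_-, r_+, a_-, a_+, A, B) over an array of S values."""
    p = params
    x, rm, rp = _roots_raw(p, S, nu)
    # boundary factors phi - (x + nu) r in the cancellation-free product
    # form x r^2 (r_other - 1), via the characteristic equation
    top_m = x * rm * rm * (rp - 1.0)  # > 0
    top_p = x * rp * rp * (rm - 1.0)  # < 0
    ratio = -(rm / rp) ** (p.N - 1) * top_m / top_p
    A = (x * rm - (p.phi + nu)) * top_p
    B = (x * rp - (p.phi + nu)) * top_m
    denom = A - B * (rm / rp) ** (p.N - 1)
    a_minus = -nu * sigma_star * top_p / denom
    a_plus = a_minus * ratio
    return rm, rp, a_minus, a_plus, A, B


def _c1_of_s(params: ModelParams, S, sigma_star: float,
             nu: float | None = None):
    """C_1 at the parametrized steady-state profile; accepts S arrays."""
    nu_c = params.nu1 if nu is None else nu
    rm, rp, am, ap, _, _ = _coefficients_raw(params, S, sigma_star, nu_c)
    return ap * rp + am * rm


def _phosphatase_balance_roots(params: ModelParams,
                               c1_total, n_scan: int = 10_000
                               ) -> list[float]:
    """All S in (0, ST) with alpha*(C1_total(S))*(ST - S) = beta*S.

    ``c1_total`` maps S to the summed singly phosphorylated complexes.
    A dense log-spaced sign scan followed by bisection captures every
    branch (up to three can coexist).
    """
    p = params
    lo, hi = p.ST * 1e-14, p.ST * (1 - 1e-12)
    grid = np.geomspace(lo, hi, n_scan)

    def g(S):
        return p.alpha * c1_total(S) * (p.ST - S) - p.beta * S

    vals = np.asarray(g(grid))
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], rtol=1e-14))
    return roots


def steady_states_by_parametrization(params: ModelParams) -> list[SteadyState]:
    """Agonist-only steady states via the scalar self-consistency in S.

    Independent route from the polynomial elimination: C_1(S) from the
    chain parametrization is substituted into the phosphatase balance
    S = ST C_1/(C_1 + beta/alpha) and all roots are located by dense
    scan plus bisection.
    """
    p = params
    if not p.agonist_only:
        raise ValueError("agonist-only route; use antagonist_steady_state")
    sigma = solve_sigma(p)
    out = []
    for S in _phosphatase_balance_roots(
            p, lambda s: _c1_of_s(p, s, sigma.sigma1)):
        par = solve_coefficients(p, S, sigma.sigma1)
        C = par.profile(p.N)
        if np.any(C <= 0):
            continue
        state = State(S, C, np.zeros(p.N + 1))
        res = float(np.abs(rhs_full(p, state).to_vector(False)).max())
        out.append(SteadyState(state, S, sigma, res))
    out.sort(key=lambda s: s.S)
    return out


@dataclass
class ResponseCurve:
    """Branch-resolved response log10 C_N over a (log10 L1, nu1) grid."""

    table: pd.DataFrame          # logL1, nu1, branch, logCN, S, stable
    fold_points: list[tuple[str, float, float]] = field(default_factory=list)

    def branch_counts(self) -> pd.Series:
        return self.table.groupby(["logL1", "nu1"]).size()


def _match_branches(prev: list[float], new: list[float]) -> list[int]:
    """Greedy nearest-neighbour branch ids for values in ``new``."""
    ids = [-1] * len(new)
    if not prev:
        return list(range(len(new)))
    taken = set()
    order = sorted(range(len(new)),
                   key=lambda i: min(abs(new[i] - q) for q in prev))
    next_id = len(prev)
    for i in order:
        cand = sorted(range(len(prev)), key=lambda k: abs(new[i] - prev[k]))
        for k in cand:
            if k not in taken:
                ids[i] = k
                taken.add(k)
                break
        else:
            ids[i] = next_id
            next_id += 1
    return ids


def response_function(params: ModelParams,
                      L1_grid: np.ndarray | None = None,
                      nu1_grid: np.ndarray | None = None,
                      classify_branches: bool = True) -> ResponseCurve:
    """Evaluate the (multi-valued) response over a parameter grid.

    Exactly one of the grids may be None, in which case the value in
    ``params`` is used.  Every branch value corresponds to an
    enumerated steady state; stability labels are attached per branch,
    and grid intervals where the branch count changes are recorded as
    fold candidates.
    """
    from .stability import classify

    p = params
    if not p.agonist_only:
        raise ValueError("response_function is agonist-only")
    L1s = np.atleast_1d(L1_grid if L1_grid is not None else p.L1).astype(float)
    nu1s = np.atleast_1d(nu1_grid if nu1_grid is not None else p.nu1
                         ).astype(float)
    sweep = "L1" if len(L1s) > 1 or nu1_grid is None else "nu1"
    rows = []
    folds = []
    for nu1 in nu1s:
        prev_S: list[float] = []
        prev_count = None
        prev_x = None
        for L1 in L1s:
            pp = p.replace(L1=L1, nu1=nu1)
            states = enumerate_steady_states(pp)
            ids = _match_branches(prev_S, [s.S for s in states])
            for bid, ss in zip(ids, states):
                stable = None
                if classify_branches:
                    stable = classify(pp, ss).stable
                rows.append({
                    "logL1": np.log10(L1), "nu1": nu1, "branch": bid,
                    "logCN": np.log10(ss.CN), "S": ss.S, "CN": ss.CN,
                    "stable": stable,
                })
            x = np.log10(L1) if sweep == "L1" else nu1
            if prev_count is not None and len(states) != prev_count:
                folds.append((sweep, prev_x, x))
            prev_S = [s.S for s in states]
            prev_count = len(states)
            prev_x = x
    return ResponseCurve(pd.DataFrame(rows), folds)


def asymptotic_small_L1(params: ModelParams, L1: float | np.ndarray
                        ) -> dict[str, np.ndarray | float]:
    """Leading-order C_N for L1 << R (kinetic-proofreading-like regime).

    With S -> 0 the chain factor tends to a constant, so

        C_N ~ { r_-^N (1 - r_-/r_+) / (1 - (r_-/r_+)^(N+1))
                * kappa R / (kappa R + nu1) } * L1 (1 + q L1/R)

    with -1/4 < q < 0.  Returns the q = 0 leading term together with
    the bracketed correction interval; on a log-log plot the leading
    term is a line of slope one.
    """
    p = params
    L1 = np.asarray(L1, dtype=float)
    if p.b > 0:
        rm, rp = characteristic_roots(p, 0.0)
        rho = rm / rp
        chain_factor = rm ** p.N * (1 - rho) / (1 - rho ** (p.N + 1))
    else:
        # x -> 0 limit: r_- -> phi/(phi+nu1), r_+ -> infinity
        chain_factor = (p.phi / (p.phi + p.nu1)) ** p.N
    pref = chain_factor * p.kappa * p.R / (p.kappa * p.R + p.nu1)
    lead = pref * L1
    return {
        "leading": lead,
        "lower": lead * (1 - 0.25 * L1 / p.R),
        "upper": lead,
        "prefactor": pref,
    }


def asymptotic_intermediate(params: ModelParams, L1: float | np.ndarray
                            ) -> dict[str, np.ndarray | float]:
    """Intermediate-regime approximation of C_N and its regime diagnostics.

    For kappa R >= 1 and L1/R <= 1, with the phosphatase level well away
    from 0 and ST,

        C_N ~ (phi beta / (alpha gamma ST))^(N/2)
              * ((kappa R + nu1)/(kappa R))^(N/2 - 1) * L1^(1 - N/2),

    so the response *decreases* with L1 for N > 2 and increases with
    nu1.  The expansion parameters eta, eta', eta'' are returned; the
    approximation carries a warning flag when eta'' is not small.
    """
    p = params
    L1 = np.asarray(L1, dtype=float)
    if p.kappa * p.R < 1:
        raise ValueError("intermediate regime requires kappa*R >= 1")
    if np.any(L1 / p.R > 1):
        raise ValueError("intermediate regime requires L1/R <= 1")
    C_star = p.beta / p.alpha
    X1 = p.kappa * p.R * L1 / (p.kappa * p.R + p.nu1)
    S_est = np.sqrt(p.phi * p.ST * X1 / (C_star * p.gamma))
    approx = ((p.phi * p.beta / (p.alpha * p.gamma * p.ST)) ** (p.N / 2)
              * ((p.kappa * p.R + p.nu1) / (p.kappa * p.R)) ** (p.N / 2 - 1)
              * L1 ** (1 - p.N / 2))
    eta = (p.phi + p.nu1) / (p.b + p.gamma * S_est)
    eta_p = np.maximum(eta, p.b / (p.gamma * S_est))
    eta_pp = np.maximum(eta_p, L1 / p.R)
    out = {"approx": approx, "eta": eta, "eta_prime": eta_p,
           "eta_doubleprime": eta_pp, "S_estimate": S_est,
           "regime_ok": bool(np.all(eta_pp < 0.3))}
    if not out["regime_ok"]:
        logger.warning("intermediate-regime expansion parameter eta'' = %.3g "
                       "is not small; approximation unreliable",
                       float(np.max(eta_pp)))
    return out


def antagonist_steady_state(params: ModelParams) -> list[SteadyState]:
    """All steady states of the full system with both ligands present.

    Both chains share S; C_1(S) and D_1(S) follow from the two
    parametrized profiles with their own dissociation rates, and S
    solves alpha (C1 + D1)(ST - S) = beta S.  All fixed points are
    located by dense scan over (0, ST).
    """
    p = params
    if p.agonist_only:
        raise ValueError("L2 = 0; use enumerate_steady_states")
    sigma = solve_sigma(p)

    def c1_total(S: float) -> float:
        return (_c1_of_s(p, S, sigma.sigma1, p.nu1)
                + _c1_of_s(p, S, sigma.sigma2, p.nu2))

    out = []
    for S in _phosphatase_balance_roots(p, c1_total):
        parC = solve_coefficients(p, S, sigma.sigma1, p.nu1)
        parD = solve_coefficients(p, S, sigma.sigma2, p.nu2)
        C, D = parC.profile(p.N), parD.profile(p.N)
        if np.any(C <= 0) or np.any(D <= 0):
            continue
        state = State(S, C, D)
        res = float(np.abs(rhs_full(p, state).to_vector(True)).max())
        out.append(SteadyState(state, S, sigma, res))
    if not out:
        raise RuntimeError("no steady state found; existence is guaranteed, "
                           "so this indicates a numerical failure")
    out.sort(key=lambda s: s.S)
    return out


def antagonist_asymptotics(params: ModelParams) -> float:
    """Leading-order C_N + D_N in the intermediate regime with antagonist.

    Obtained from the agonist-only formula by the replacement
    kappa R L1/(kappa R + nu1) -> kappa R L1/(kappa R + nu1)
                                  + kappa R L2/(kappa R + nu2).
    """
    p = params
    kR = p.kappa * p.R
    X = kR * p.L1 / (kR + p.nu1) + kR * p.L2 / (kR + p.nu2)
    C_star = p.beta / p.alpha
    return float((p.phi * C_star / (p.gamma * p.ST)) ** (p.N / 2)
                 * X ** (1 - p.N / 2))
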
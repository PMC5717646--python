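"""Linearization and eigenvalue classification of steady states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, State
from .steady_states import SteadyState, enumerate_steady_states

__all__ = [
    "StabilityReport",
    "jacobian",
    "classify",
    "find_damped_oscillation_params",
    "limiting_jacobian_n1",
]


@dataclass
class StabilityReport:
    """Eigenvalue structure of a linearized steady state.

    ``label`` is one of stable-node, stable-focus, saddle, unstable,
    marginal; ``unstable_dim`` counts eigenvalues with real part above
    the marginality tolerance; ``oscillatory`` is set when the dominant
    (rightmost) eigenvalue pair is complex.
    """

    eigenvalues: np.ndarray
    label: str
    unstable_dim: int
    oscillatory: bool

    @property
    def stable(self) -> bool:
        return self.label in ("stable-node", "stable-focus")


def jacobian(params: ModelParams, state: State) -> np.ndarray:
    """Analytic Jacobian of the full right-hand side.

    Variables are ordered (S, C_0..C_N) for agonist-only instances and
    (S, C_0..C_N, D_0..D_N) otherwise.
    """
    p = params
    N = p.N
    include_D = not p.agonist_only
    n = 1 + (N + 1) * (2 if include_D else 1)
    S, C, D = state.S, state.C, state.D
    x = p.b + p.gamma * S
    J = np.zeros((n, n))
    iC = 1              # index of C_0
    iD = 1 + (N + 1)    # index of D_0 (when present)

    D1 = D[1] if include_D else 0.0
    # dS/dt = alpha (C1 + D1)(ST - S) - beta S
    J[0, 0] = -p.alpha * (C[1] + D1) - p.beta
    J[0, iC + 1] = p.alpha * (p.ST - S)
    if include_D:
        J[0, iD + 1] = p.alpha * (p.ST - S)

    free_R = p.R - C.sum() - D.sum()

    def fill_chain(base: int, Z: np.ndarray, L_tot: float, nu: float) -> None:
        free_L = L_tot - Z.sum()
        # Z_0 row: binding term depends on own chain through both free
        # ligand and free receptor, on the other chain only through
        # free receptor.
        J[base, 0] = p.gamma * Z[1]
        for k in range(N + 1):
            J[base, base + k] = -p.kappa * free_R - p.kappa * free_L
        if include_D:
            other = iD if base == iC else iC
            for k in range(N + 1):
                J[base, other + k] = -p.kappa * free_L
        J[base, base + 0] += -(p.phi + nu)
        J[base, base + 1] += x
        # middle rows
        for j in range(1, N):
            r = base + j
            J[r, 0] = p.gamma * (Z[j + 1] - Z[j])
            J[r, base + j - 1] = p.phi
            J[r, base + j] = -(p.phi + x + nu)
            J[r, base + j + 1] = x
        # top row
        r = base + N
        J[r, 0] = -p.gamma * Z[N]
        J[r, base + N - 1] = p.phi
        J[r, base + N] = -(x + nu)

    fill_chain(iC, C, p.L1, p.nu1)
    if include_D:
        fill_chain(iD, D, p.L2, p.nu2)
    return J


def classify(params: ModelParams, steady_state: SteadyState | State,
             marginal_rtol: float = 1e-8) -> StabilityReport:
    """Classify a steady state from the eigenvalues of its Jacobian."""
    state = (steady_state.state if isinstance(steady_state, SteadyState)
             else steady_state)
    eig = np.linalg.eigvals(jacobian(params, state))
    return _classify_eigenvalues(eig, marginal_rtol)


def _classify_eigenvalues(eig: np.ndarray, marginal_rtol: float = 1e-8
                          ) -> StabilityReport:
    scale = max(float(np.abs(eig).max()), 1e-300)
    tol = marginal_rtol * scale
    re = eig.real
    n_pos = int(np.sum(re > tol))
    n_neg = int(np.sum(re < -tol))
    dominant = eig[np.argsort(-re)][:2]
    oscillatory = bool(np.any(np.abs(dominant.imag) > tol))
    if n_pos + n_neg < len(eig):
        label = "marginal"
    elif n_pos == 0:
        label = "stable-focus" if oscillatory else "stable-node"
    elif n_neg == 0:
        label = "unstable"
    else:
        label = "saddle"
    return StabilityReport(eigenvalues=eig, label=label,
                           unstable_dim=n_pos, oscillatory=oscillatory)


def limiting_jacobian_n1(params: ModelParams, S: float, C1: float
                         ) -> np.ndarray:
    """2x2 Jacobian of the limiting (S, C1) system for N = 1."""
    p = params
    x = p.b + p.gamma * S
    return np.array([
        [-p.alpha * C1 - p.beta, p.alpha * (p.ST - S)],
        [-p.gamma * C1, -(p.phi + x + p.nu1)],
    ])


_DEFAULT_N1_TEMPLATE = dict(alpha=0.1, beta=1.0, gamma=1.0, phi=1.0, b=0.0,
                            kappa=1.0, nu1=0.1, nu2=1.0, L1=1.0, L2=0.0,
                            R=1.0, ST=10.0, N=1)


def find_damped_oscillation_params(template: ModelParams | None = None,
                                   beta_bracket: tuple[float, float] = (1e-8, 1e4),
                                   ) -> tuple[ModelParams, StabilityReport]:
    """Parameters for which the N=1 approach to equilibrium oscillates.

    Solves, by bisection in beta, the balance

        alpha C1 + beta = phi + b + gamma S + nu1

    imposed at the self-consistent steady state.  On that locus the
    discriminant of the 2x2 characteristic equation reduces to
    -4 alpha gamma (ST - S) C1 < 0, so the eigenvalues are a complex
    pair with negative real part: damped oscillations.
    """
    if template is None:
        template = ModelParams(**_DEFAULT_N1_TEMPLATE)
    p0 = template
    if p0.N != 1 or not p0.agonist_only:
        raise ValueError("requires an agonist-only N = 1 template")

    def balance(beta: float) -> float:
        p = p0.replace(beta=beta)
        ss = enumerate_steady_states(p)[0]
        S, C1 = ss.S, ss.C[1]
        return p.alpha * C1 + beta - (p.phi + p.b + p.gamma * S + p.nu1)

    lo, hi = beta_bracket
    if balance(lo) * balance(hi) > 0:
        raise RuntimeError(
            "beta bracket does not straddle the oscillation balance on "
            "this parameter slice; no solution reported")
    beta = brentq(balance, lo, hi, rtol=1e-14)
    params = p0.replace(beta=beta)
    ss = enumerate_steady_states(params)[0]
    eig = np.linalg.eigvals(limiting_jacobian_n1(params, ss.S, ss.C[1]))
    return params, _classify_eigenvalues(eig)
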
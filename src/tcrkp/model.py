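"""Mass-action model of early T-cell receptor signalling.

The model tracks a chain of N sequential phosphorylation states of the
TCR complex bound to an agonist ligand (concentrations ``C_0 .. C_N``)
and, optionally, to an antagonist ligand (``D_0 .. D_N``), together with
the active form ``S`` of the phosphatase SHP-1.  Receptor complexes are
phosphorylated at rate ``phi``, dephosphorylated basally at rate ``b``
and by active SHP-1 at rate ``gamma * S``; ligand binds free receptor at
rate ``kappa`` and dissociates at rate ``nu1`` (agonist) or ``nu2``
(antagonist).  SHP-1 is activated by singly phosphorylated complexes at
rate ``alpha`` and decays at rate ``beta``.  Conservation of total
ligand (``L1``, ``L2``), receptor (``R``) and phosphatase (``ST``) has
already been used to eliminate the free species, so the feasible region
is the set where all concentrations and conservation slacks are
positive.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "State",
    "FeasibilityMargins",
    "rhs_full",
    "rhs_sigma",
    "rhs_limiting",
    "feasibility",
    "load_params",
    "save_params",
    "read_states_csv",
    "write_states_csv",
]

_PARAM_KEYS = (
    "alpha", "beta", "gamma", "phi", "b", "kappa",
    "nu1", "nu2", "L1", "L2", "R", "ST", "N",
)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and conserved totals defining one model instance.

    Units are arbitrary (concentration and time scales are not fixed by
    the model).  ``N`` is the number of phosphorylation sites; ``L2 = 0``
    marks an agonist-only instance, in which the antagonist chain is
    inert.
    """

    alpha: float
    beta: float
    gamma: float
    phi: float
    b: float
    kappa: float
    nu1: float
    nu2: float
    L1: float
    L2: float
    R: float
    ST: float
    N: int

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "phi", "kappa", "nu1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0 (0 = kinetic proofreading "
                             "limit, no feedback)")
        if self.b < 0:
            raise ValueError("basal dephosphorylation rate b must be >= 0")
        if self.b == 0:
            # b > 0 in the general model; b = 0 is admitted because the
            # three-steady-state construction uses it.
            logger.warning("b = 0: basal dephosphorylation disabled")
        if self.L1 <= 0:
            raise ValueError("total agonist L1 must be positive")
        if self.L2 < 0:
            raise ValueError("total antagonist L2 must be >= 0")
        if self.L2 > 0 and self.nu2 <= 0:
            raise ValueError("nu2 must be positive when antagonist is present")
        if self.R <= 0 or self.ST <= 0:
            raise ValueError("totals R and ST must be positive")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError("chain length N must be an integer >= 1")

    @property
    def agonist_only(self) -> bool:
        return self.L2 == 0

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: (int(self.N) if k == "N" else float(getattr(self, k)))
                for k in _PARAM_KEYS}


@dataclass
class State:
    """Concentration vector (S, C_0..C_N, D_0..D_N)."""

    S: float
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.C.shape != self.D.shape or self.C.ndim != 1:
            raise ValueError("C and D must be 1-d arrays of equal length")

    @property
    def N(self) -> int:
        return len(self.C) - 1

    @classmethod
    def zeros(cls, N: int) -> "State":
        return cls(0.0, np.zeros(N + 1), np.zeros(N + 1))

    @classmethod
    def from_vector(cls, vec: np.ndarray, N: int, include_D: bool) -> "State":
        vec = np.asarray(vec, dtype=float)
        C = vec[1:N + 2]
        D = vec[N + 2:2 * N + 3] if include_D else np.zeros(N + 1)
        return cls(float(vec[0]), C.copy(), D.copy())

    def to_vector(self, include_D: bool) -> np.ndarray:
        parts = [np.array([self.S]), self.C]
        if include_D:
            parts.append(self.D)
        return np.concatenate(parts)

    def copy(self) -> "State":
        return State(self.S, self.C.copy(), self.D.copy())


@dataclass
class FeasibilityMargins:
    """Slack of a state with respect to the feasible-region boundary.

    The six margins are ``S``, ``ST - S``, ``L1 - sum C_j``,
    ``L2 - sum D_j``, ``R - sum(C_j + D_j)`` and the smallest complex
    concentration.  For agonist-only instances the inert antagonist
    block is excluded.
    """

    S: float
    ST_minus_S: float
    L1_slack: float
    L2_slack: float | None
    R_slack: float
    min_complex: float
    tol: float = 1e-10

    def as_array(self) -> np.ndarray:
        vals = [self.S, self.ST_minus_S, self.L1_slack, self.R_slack,
                self.min_complex]
        if self.L2_slack is not None:
            vals.insert(3, self.L2_slack)
        return np.array(vals)

    @property
    def min(self) -> float:
        return float(self.as_array().min())

    @property
    def classification(self) -> str:
        m = self.min
        if m > self.tol:
            return "interior"
        if m >= -self.tol:
            return "boundary"
        return "outside"


def _check_dims(params: ModelParams, state: State) -> None:
    if state.N != params.N:
        raise ValueError(
            f"state has N={state.N} but params require N={params.N}")


def rhs_full(params: ModelParams, state: State) -> State:
    """Time derivatives of the full mass-action system.

    Returns a :class:`State` holding (dS/dt, dC/dt, dD/dt).  For
    agonist-only instances with D = 0 the antagonist block is
    identically zero.
    """
    _check_dims(params, state)
    p = params
    S, C, D = state.S, state.C, state.D
    if p.ST - S < 0:
        logger.warning("state has S > ST (outside feasible region)")
    x = p.b + p.gamma * S  # total dephosphorylation rate
    free_R = p.R - (C.sum() + D.sum())

    dS = p.alpha * (C[1] + D[1]) * (p.ST - S) - p.beta * S if p.N >= 1 else 0.0

    def chain(Z: np.ndarray, L_tot: float, nu: float) -> np.ndarray:
        dZ = np.empty_like(Z)
        dZ[0] = (p.kappa * (L_tot - Z.sum()) * free_R
                 + x * Z[1] - (p.phi + nu) * Z[0])
        if p.N >= 2:
            j = np.arange(1, p.N)
            dZ[1:p.N] = (p.phi * Z[j - 1] + x * Z[j + 1]
                         - (p.phi + x + nu) * Z[j])
        dZ[p.N] = p.phi * Z[p.N - 1] - (x + nu) * Z[p.N]
        return dZ

    dC = chain(C, p.L1, p.nu1)
    if p.agonist_only and not D.any():
        dD = np.zeros_like(D)
    else:
        dD = chain(D, p.L2, p.nu2)
    return State(dS, dC, dD)


def rhs_sigma(params: ModelParams, sigma1: float, sigma2: float
              ) -> tuple[float, float]:
    """Derivatives of the total bound-ligand pools (Sigma1, Sigma2).

    Summing the chain equations makes the pools close on themselves:
    each pool grows by binding of free ligand to free receptor and
    shrinks by dissociation.
    """
    p = params
    if not (0.0 <= sigma1 <= p.L1):
        raise ValueError("sigma1 outside [0, L1]")
    if not (0.0 <= sigma2 <= max(p.L2, 0.0)):
        raise ValueError("sigma2 outside [0, L2]")
    if sigma1 + sigma2 > p.R:
        raise ValueError("sigma1 + sigma2 exceeds R")
    free_R = p.R - sigma1 - sigma2
    d1 = p.kappa * (p.L1 - sigma1) * free_R - p.nu1 * sigma1
    d2 = p.kappa * (p.L2 - sigma2) * free_R - p.nu2 * sigma2
    return d1, d2


def rhs_limiting(params: ModelParams, sigma1_star: float, sigma2_star: float,
                 S: float, C: Sequence[float], D: Sequence[float] | None = None
                 ) -> tuple[float, np.ndarray, np.ndarray | None]:
    """Right-hand side of the limiting system on the invariant set.

    On the attractor the bound-ligand pools have relaxed to their unique
    equilibrium values ``sigma1_star``/``sigma2_star``, which lets C_0
    and D_0 be eliminated.  ``C`` holds C_1..C_N (and ``D`` likewise).
    Returns (dS, dC, dD); dD is None for agonist-only input.
    """
    p = params
    C = np.asarray(C, dtype=float)
    if len(C) != p.N:
        raise ValueError(f"expected C_1..C_N ({p.N} values), got {len(C)}")
    has_D = D is not None
    if has_D:
        D = np.asarray(D, dtype=float)
        if len(D) != p.N:
            raise ValueError(f"expected D_1..D_N ({p.N} values)")
    x = p.b + p.gamma * S
    D1 = D[0] if has_D else 0.0
    dS = p.alpha * (C[0] + D1) * (p.ST - S) - p.beta * S

    def chain(Z: np.ndarray, sig: float, nu: float) -> np.ndarray:
        if p.N == 1:
            # two-equation system: dC1 = phi*(sigma* - C1) - (b+gS+nu)C1
            return np.array([p.phi * sig - (p.phi + x + nu) * Z[0]])
        dZ = np.empty(p.N)
        # index 0 of Z is C_1
        tail = Z[2:].sum() if p.N >= 3 else 0.0
        dZ[0] = (p.phi * sig + (x - p.phi) * Z[1]
                 - (2 * p.phi + x + nu) * Z[0] - p.phi * tail)
        if p.N >= 3:
            j = np.arange(1, p.N - 1)
            dZ[1:p.N - 1] = (p.phi * Z[j - 1] + x * Z[j + 1]
                             - (p.phi + x + nu) * Z[j])
        dZ[p.N - 1] = p.phi * Z[p.N - 2] - (x + nu) * Z[p.N - 1]
        return dZ

    dC = chain(C, sigma1_star, p.nu1)
    dD = chain(D, sigma2_star, p.nu2) if has_D else None
    return dS, dC, dD


def feasibility(params: ModelParams, state: State) -> FeasibilityMargins:
    """Slacks of ``state`` with respect to the feasible-region boundary."""
    _check_dims(params, state)
    p = params
    C, D = state.C, state.D
    include_D = not (p.agonist_only and not D.any())
    min_complex = float(min(C.min(), D.min()) if include_D else C.min())
    return FeasibilityMargins(
        S=float(state.S),
        ST_minus_S=float(p.ST - state.S),
        L1_slack=float(p.L1 - C.sum()),
        L2_slack=float(p.L2 - D.sum()) if include_D else None,
        R_slack=float(p.R - C.sum() - D.sum()),
        min_complex=min_complex,
    )


# ---------------------------------------------------------------------------
# configuration and state I/O

def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set from a flat JSON or YAML key/value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter keys")
    missing = [k for k in _PARAM_KEYS if k not in raw]
    if missing:
        raise KeyError(f"{path}: missing parameter keys {missing}")
    extra = [k for k in raw if k not in _PARAM_KEYS]
    if extra:
        raise KeyError(f"{path}: unknown parameter keys {extra}")
    kwargs = {k: (int(raw[k]) if k == "N" else float(raw[k]))
              for k in _PARAM_KEYS}
    return ModelParams(**kwargs)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def _state_header(N: int, include_D: bool) -> list[str]:
    cols = ["S"] + [f"C{j}" for j in range(N + 1)]
    if include_D:
        cols += [f"D{j}" for j in range(N + 1)]
    return cols


def write_states_csv(states: Sequence[State], path: str | Path,
                     extra_columns: dict[str, Sequence] | None = None) -> None:
    """Write states as CSV with header S,C0..CN[,D0..DN]."""
    if not states:
        raise ValueError("no states to write")
    N = states[0].N
    include_D = any(s.D.any() for s in states)
    header = _state_header(N, include_D)
    extra = extra_columns or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header + list(extra))
        for i, s in enumerate(states):
            row = list(s.to_vector(include_D))
            row += [extra[k][i] for k in extra]
            w.writerow(row)


def read_states_csv(path: str | Path) -> list[State]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        return []
    cols = rows[0].keys()
    N = max(int(c[1:]) for c in cols if c.startswith("C") and c[1:].isdigit())
    include_D = f"D0" in cols
    states = []
    for r in rows:
        C = np.array([float(r[f"C{j}"]) for j in range(N + 1)])
        D = (np.array([float(r[f"D{j}"]) for j in range(N + 1)])
             if include_D else np.zeros(N + 1))
        states.append(State(float(r["S"]), C, D))
    return states
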
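"""Time integration with feasibility diagnostics.

The rate constants of interest span many orders of magnitude, so the
system is integrated with a stiff-capable method (LSODA with the
analytic Jacobian) and, by default, until the right-hand side has
relaxed below a relative tolerance or a long horizon is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ModelParams, State, rhs_full, feasibility
from .stability import jacobian
from .steady_states import enumerate_steady_states

__all__ = ["Trajectory", "integrate", "basin_sample", "oscillation_diagnostic",
           "sample_feasible_state"]

T_MAX_DEFAULT = 1e6


@dataclass
class Trajectory:
    """An integrated orbit with feasibility bookkeeping."""

    t: np.ndarray
    states: np.ndarray          # one packed state vector per row
    columns: list[str]
    margins: np.ndarray         # min feasibility margin at each time
    converged: bool
    terminal: State
    terminal_rhs_norm: float

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    def observable(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.columns)
        df.insert(0, "t", self.t)
        return df


def _rhs_norm(params: ModelParams, state: State, include_D: bool) -> float:
    d = rhs_full(params, state).to_vector(include_D)
    scale = max(1.0, float(np.abs(state.to_vector(include_D)).max()))
    return float(np.abs(d).max()) / scale


def integrate(params: ModelParams, initial: State, t_end: float | None = None,
              rtol: float = 1e-9, atol: float = 1e-12,
              method: str = "LSODA", converge_rtol: float = 1e-10
              ) -> Trajectory:
    """Integrate from ``initial``; stop once the flow has relaxed.

    With ``t_end`` omitted the orbit is extended in expanding windows
    until the scaled right-hand side drops below ``converge_rtol`` or
    t = 1e6 model time units.
    """
    p = params
    include_D = not p.agonist_only
    y0 = initial.to_vector(include_D)
    N = p.N

    def f(t, y):
        return rhs_full(p, State.from_vector(y, N, include_D)
                        ).to_vector(include_D)

    def jac(t, y):
        return jacobian(p, State.from_vector(y, N, include_D))

    cols = ["S"] + [f"C{j}" for j in range(N + 1)]
    if include_D:
        cols += [f"D{j}" for j in range(N + 1)]

    ts = [np.array([0.0])]
    ys = [y0[None, :]]
    t0 = 0.0
    horizon = t_end if t_end is not None else T_MAX_DEFAULT
    window = horizon if t_end is not None else min(10.0, horizon)
    converged = False
    y = y0
    while True:
        sol = solve_ivp(f, (t0, t0 + window), y, method=method, jac=jac,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            break
        ts.append(sol.t[1:])
        ys.append(sol.y.T[1:])
        t0 = sol.t[-1]
        y = sol.y[:, -1]
        state = State.from_vector(y, N, include_D)
        if _rhs_norm(p, state, include_D) < converge_rtol:
            converged = True
            break
        if t0 >= horizon - 1e-12:
            break
        window = min(window * 10, horizon - t0)

    t = np.concatenate(ts)
    Y = np.vstack(ys)
    margins = np.array([
        feasibility(p, State.from_vector(row, N, include_D)).min for row in Y])
    terminal = State.from_vector(Y[-1], N, include_D)
    return Trajectory(t=t, states=Y, columns=cols, margins=margins,
                      converged=converged, terminal=terminal,
                      terminal_rhs_norm=_rhs_norm(p, terminal, include_D))


def sample_feasible_state(params: ModelParams, rng: np.random.Generator
                          ) -> State:
    """Draw a random state from the interior of the feasible region."""
    p = params
    S = rng.uniform(0, p.ST)
    cap1 = min(p.L1, p.R)
    w = rng.random(p.N + 1)
    C = w / w.sum() * rng.uniform(0, cap1)
    if p.agonist_only:
        D = np.zeros(p.N + 1)
    else:
        cap2 = min(p.L2, p.R - C.sum())
        w = rng.random(p.N + 1)
        D = w / w.sum() * rng.uniform(0, max(cap2, 0.0))
    return State(S, C, D)


def basin_sample(params: ModelParams, n_starts: int, seed: int,
                 t_end: float | None = None,
                 match_rtol: float = 1e-4) -> pd.DataFrame:
    """Estimate basins of attraction by multistart integration.

    Each random interior start is integrated until convergence and the
    terminal state matched to the nearest enumerated steady state.
    Returns one row per steady state with the fraction of starts it
    attracted; non-convergent or unmatched starts are reported
    separately.
    """
    p = params
    rng = np.random.default_rng(seed)
    targets = enumerate_steady_states(p)
    counts = np.zeros(len(targets), dtype=int)
    unmatched = 0
    nonconverged = 0
    include_D = not p.agonist_only
    for _ in range(n_starts):
        traj = integrate(p, sample_feasible_state(p, rng), t_end=t_end)
        if not traj.converged and traj.terminal_rhs_norm > 1e-7:
            nonconverged += 1
            continue
        term = traj.terminal.to_vector(include_D)
        best, dist = None, np.inf
        for i, ss in enumerate(targets):
            d = np.abs(term - ss.state.to_vector(include_D)).max()
            if d < dist:
                best, dist = i, d
        scale = max(1.0, np.abs(term).max())
        if dist < match_rtol * scale:
            counts[best] += 1
        else:
            unmatched += 1
    rows = [{"S": ss.S, "CN": ss.CN, "n": int(c),
             "fraction": c / n_starts}
            for ss, c in zip(targets, counts)]
    df = pd.DataFrame(rows)
    df.attrs["unmatched"] = unmatched
    df.attrs["nonconverged"] = nonconverged
    return df


def oscillation_diagnostic(traj: Trajectory, observable: str = "S",
                           min_extrema: int = 2, decay_slack: float = 1.05
                           ) -> bool | None:
    """Flag damped oscillations in an observable of a converged orbit.

    True when the observable's derivative changes sign at least twice
    with (approximately) geometrically decaying excursion amplitudes
    about the limit; None when the trajectory is too short to decide.
    """
    if len(traj.t) < 8:
        return None
    y = traj.observable(observable)
    y_inf = y[-1]
    dy = np.diff(y)
    sign = np.sign(dy)
    sign = sign[sign != 0]
    flips = np.nonzero(sign[1:] != sign[:-1])[0]
    if len(flips) < min_extrema:
        return False
    # amplitudes of the excursions at interior extrema
    dz = np.sign(np.diff(y))
    idx = np.nonzero(dz[1:] != dz[:-1])[0] + 1
    amps = np.abs(y[idx] - y_inf)
    amps = amps[amps > 0]
    if len(amps) < min_extrema:
        return False
    ratios = amps[1:] / amps[:-1]
    return bool(np.all(ratios < decay_slack) and amps[-1] < amps[0])
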
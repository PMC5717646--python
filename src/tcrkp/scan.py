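"""One-parameter bifurcation scans and config-driven runs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ModelParams, load_params
from .steady_states import enumerate_steady_states

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "scan_parameter", "refine_fold", "run_config",
           "ConfigError", "parse_grid"]

_SCANNABLE = ("L1", "L2", "nu1", "nu2", "ST", "R", "kappa", "alpha", "beta",
              "gamma", "phi", "b")


@dataclass
class ScanResult:
    """Branches of steady states along a swept parameter."""

    name: str
    grid: np.ndarray
    table: pd.DataFrame                       # value, S, CN, stable, count
    fold_intervals: list[tuple[float, float]] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return (self.table.groupby("value").size()
                .reindex(self.grid, fill_value=0).to_numpy())


def _states_at(params: ModelParams, name: str, value: float):
    return enumerate_steady_states(params.replace(**{name: float(value)}))


def scan_parameter(params: ModelParams, name: str, grid: np.ndarray,
                   classify_branches: bool = True,
                   refine: bool = True) -> ScanResult:
    """Sweep one parameter, tracking all steady-state branches.

    Grid intervals where the number of steady states changes contain a
    fold (saddle-node) point; these are refined by bisection on the
    root count.
    """
    from .stability import classify

    if name not in _SCANNABLE:
        raise ValueError(f"cannot scan parameter {name!r}")
    grid = np.asarray(grid, dtype=float)
    rows = []
    counts = []
    for v in grid:
        pp = params.replace(**{name: float(v)})
        states = enumerate_steady_states(pp)
        counts.append(len(states))
        for ss in states:
            stable = classify(pp, ss).stable if classify_branches else None
            rows.append({"value": v, "S": ss.S, "CN": ss.CN,
                         "stable": stable, "count": len(states)})
        logger.info("%s=%g: %d steady state(s)", name, v, len(states))
    folds = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = grid[i], grid[i + 1]
            if refine:
                lo, hi = refine_fold(params, name, lo, hi)
            folds.append((float(lo), float(hi)))
    return ScanResult(name, grid, pd.DataFrame(rows), folds)


def refine_fold(params: ModelParams, name: str, lo: float, hi: float,
                iters: int = 40) -> tuple[float, float]:
    """Bisection on the steady-state count to bracket a fold point."""
    n_lo = len(_states_at(params, name, lo))
    for _ in range(iters):
        mid = np.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        if len(_states_at(params, name, mid)) == n_lo:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(abs(hi), 1.0):
            break
    return float(lo), float(hi)


class ConfigError(ValueError):
    """A run configuration is missing or misusing a key."""


def parse_grid(spec) -> np.ndarray:
    """Parse a grid spec: list of numbers or "start:stop:COUNT[log|lin]"."""
    if isinstance(spec, (list, tuple, np.ndarray)):
        return np.asarray(spec, dtype=float)
    if not isinstance(spec, str):
        raise ConfigError(f"cannot parse grid spec {spec!r}")
    parts = spec.split(":")
    if len(parts) != 3:
        raise ConfigError(f"grid spec {spec!r} must be start:stop:COUNT[log]")
    start, stop = float(parts[0]), float(parts[1])
    tail = parts[2]
    log = tail.endswith("log")
    n = int(tail.removesuffix("log").removesuffix("lin"))
    return np.geomspace(start, stop, n) if log else np.linspace(start, stop, n)


def _require(cfg: dict, key: str, where: str = "config"):
    if key not in cfg:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return cfg[key]


def run_config(path: str | Path) -> dict:
    """Run the task described by a YAML/JSON config; return the manifest.

    The config names a task (steady_states | simulate | response | scan),
    the model parameters (inline mapping under ``model`` or a file path
    under ``model_file``), an output directory and task options.
    Outputs are deterministic: identical configs give identical CSVs.
    """
    from .dynamics import integrate
    from .model import State, write_states_csv
    from .response import response_function
    from .stability import classify

    path = Path(path)
    cfg = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    task = _require(cfg, "task", str(path))
    if "model" in cfg:
        try:
            params = ModelParams(**{k: (int(v) if k == "N" else float(v))
                                    for k, v in cfg["model"].items()})
        except TypeError as exc:
            raise ConfigError(f"{path}: model: {exc}") from None
    elif "model_file" in cfg:
        params = load_params(path.parent / cfg["model_file"])
    else:
        raise ConfigError(f"{path}: missing required key 'model' or "
                          "'model_file'")
    outdir = Path(_require(cfg, "out", str(path)))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    outputs: list[str] = []

    if task == "steady_states":
        states = enumerate_steady_states(params)
        labels = [classify(params, s).label for s in states]
        write_states_csv([s.state for s in states],
                         outdir / "states.csv",
                         extra_columns={
                             "residual": [s.residual for s in states],
                             "stability": labels})
        outputs.append("states.csv")
    elif task == "simulate":
        opts = cfg.get("simulate", {})
        init = _require(opts, "init", "simulate")
        state = State(float(init["S"]),
                      np.asarray(init["C"], dtype=float),
                      np.asarray(init.get("D", np.zeros(params.N + 1)),
                                 dtype=float))
        traj = integrate(params, state, t_end=opts.get("t_end"))
        traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
        outputs.append("trajectory.csv")
    elif task == "response":
        opts = cfg.get("response", {})
        L1_grid = parse_grid(opts["l1_grid"]) if "l1_grid" in opts else None
        nu1_grid = parse_grid(opts["nu1_grid"]) if "nu1_grid" in opts else None
        if L1_grid is None and nu1_grid is None:
            raise ConfigError("response: missing required key 'l1_grid' or "
                              "'nu1_grid'")
        curve = response_function(params, L1_grid, nu1_grid)
        curve.table.to_csv(outdir / "response.csv", index=False)
        outputs.append("response.csv")
    elif task == "scan":
        opts = cfg.get("scan", {})
        result = scan_parameter(params, _require(opts, "parameter", "scan"),
                                parse_grid(_require(opts, "grid", "scan")))
        result.table.to_csv(outdir / "scan.csv", index=False)
        outputs.append("scan.csv")
    else:
        raise ConfigError(f"{path}: unknown task {task!r}")

    manifest = {"task": task, "params": params.to_dict(), "seed": seed,
                "version": __version__, "outputs": outputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
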
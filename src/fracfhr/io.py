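"""CSV/JSON/YAML readers and writers plus run manifests.

Trajectories are written as plain CSV (12 significant digits, fixed header)
with a JSON sidecar carrying the solver configuration, so any run can be
reproduced bit-for-bit from its output directory.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupling import CoupledTrajectory
from .solver import SolverConfig, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_coupled_trajectory",
    "write_manifest",
    "load_config_file",
]

_FLOAT_FMT = "%.12g"
_SINGLE_COLUMNS = ("t", "v", "w", "y")
_COUPLED_COLUMNS = ("t", "v1", "w1", "y1", "v2", "w2", "y2")


def _write_csv(path: Path, header: tuple[str, ...], table: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        np.savetxt(fh, table, fmt=_FLOAT_FMT, delimiter=",")


def write_trajectory(path: str | Path, traj: Trajectory, sidecar: bool = True) -> Path:
    """Write t,v,w,y CSV; a JSON sidecar (<name>.config.json) holds the config."""
    path = Path(path)
    table = np.column_stack([traj.times, traj.states])
    if traj.states.shape[1] != 3:
        raise ValueError("write_trajectory expects a single-neuron (3-variable) trajectory")
    _write_csv(path, _SINGLE_COLUMNS, table)
    if sidecar:
        _write_sidecar(path, traj.config)
    return path


def _write_sidecar(path: Path, cfg: SolverConfig) -> None:
    from . import __version__

    meta = {
        "alpha": cfg.alpha,
        "dt": cfg.dt,
        "n_steps": cfg.n_steps,
        "seed": cfg.seed,
        "perturbation_scale": cfg.perturbation_scale,
        "initial_state": list(cfg.initial_state) if cfg.initial_state else None,
        "memory_window": cfg.memory_window,
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".config.json").write_text(json.dumps(meta, indent=2))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    The sidecar, if present, restores the solver configuration; otherwise a
    minimal config is reconstructed from the time grid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    times = df["t"].to_numpy()
    states = df[list(df.columns[1:])].to_numpy()
    sidecar = path.with_suffix(path.suffix + ".config.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        cfg = SolverConfig(
            alpha=meta["alpha"],
            n_steps=meta["n_steps"],
            dt=meta["dt"],
            seed=meta.get("seed", 0),
            perturbation_scale=meta.get("perturbation_scale", 1.0),
            initial_state=tuple(meta["initial_state"]) if meta.get("initial_state") else None,
            memory_window=meta.get("memory_window"),
        )
    else:
        dt = float(times[1] - times[0]) if times.size > 1 else 0.1
        cfg = SolverConfig(alpha=1.0, n_steps=max(1, times.size - 1), dt=dt)
    return Trajectory(times=times, states=states, config=cfg)


def write_coupled_trajectory(path: str | Path, traj: CoupledTrajectory) -> Path:
    path = Path(path)
    table = np.column_stack([traj.times, traj.states1, traj.states2])
    _write_csv(path, _COUPLED_COLUMNS, table)
    return path


def write_manifest(directory: str | Path, subcommand: str, config: dict) -> Path:
    """Emit manifest.json naming the subcommand, full config and version."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_config_file(path: str | Path) -> dict:
    """Flat key-value config (YAML); CLI flags override these entries."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return data
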
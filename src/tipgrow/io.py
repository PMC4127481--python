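"""Trajectory, summary and manifest writers (CSV + JSON sidecars)."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import Parameters
from .simulator import Trajectory
from .oscillations import (detect_oscillation, OscillationSettings,
                           InsufficientDataError)

#: column -> unit, documented in the CSV header comment
COLUMN_UNITS = {
    "t": "s", "v": "m^3", "P": "Pa", "L": "m", "eta": "Pa s", "h": "m",
    "Ca_i": "M", "H_i": "M", "K_i": "M", "Cl_i": "M", "V_m": "V",
    "p_open_Ca": "-", "p_open_K": "-", "n_vg2": "-", "Osm_i": "M",
    "r": "m", "pi_i": "Pa", "pi_o": "Pa", "phi": "Pa^-1 s^-1",
    "osmotic_inflow": "m^3 s^-1", "turgor_outflow": "m^3 s^-1",
    "net_water": "m^3 s^-1", "wall_chamber_rate": "m^3 s^-1",
    "dP_dt": "Pa s^-1", "growth_rate": "m s^-1",
    "growth_rate_um_min": "um min^-1", "dvdt_um3_s": "um^3 s^-1",
}


def config_hash(params: Parameters, protocol_name: str = "",
                extra: dict | None = None) -> str:
    """Stable short hash of a parameter set (and optional run context)."""
    doc = {"parameters": params.to_dict(), "protocol": protocol_name}
    if extra:
        doc["extra"] = extra
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path, header_comment: bool = True
                     ) -> Path:
    """Write the dense trajectory as CSV (units in a ``#`` header line)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            units = ", ".join(f"{c} [{COLUMN_UNITS.get(c, '?')}]"
                              for c in traj.data.columns)
            fh.write(f"# tipgrow trajectory; columns: {units}\n")
        traj.data.to_csv(fh, index=False)
    return path


def read_trajectory(csv_path, params: Parameters | None = None) -> Trajectory:
    """Load a trajectory written by :func:`write_trajectory`.

    Parameters are taken from the JSON sidecar (``<stem>.meta.json``) when
    present, else from ``params``.
    """
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path, comment="#")
    meta_path = csv_path.with_suffix(".meta.json")
    name = "loaded"
    if params is None:
        if not meta_path.exists():
            raise FileNotFoundError(
                f"no parameters given and no sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        params = Parameters.from_dict(meta["parameters"])
        name = meta.get("protocol", name)
    return Trajectory(t=data["t"].to_numpy(), data=data, params=params,
                      protocol_name=name)


def write_run_metadata(traj: Trajectory, path, solver_settings=None,
                       command: str = "") -> Path:
    path = Path(path)
    meta = {
        "parameters": traj.params.to_dict(),
        "protocol": traj.protocol_name,
        "config_hash": config_hash(traj.params, traj.protocol_name),
        "command": command,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if solver_settings is not None:
        meta["solver"] = {"rtol": solver_settings.rtol,
                          "dt_sample": solver_settings.dt_sample,
                          "method": solver_settings.method}
    path.write_text(json.dumps(meta, indent=2, default=str))
    return path


def oscillation_summary(traj: Trajectory, tail: float = 0.5,
                        variables: tuple = ("growth_rate_um_min",
                                            "dvdt_um3_s", "P", "phi",
                                            "Ca_i", "V_m"),
                        settings: OscillationSettings | None = None) -> dict:
    """Per-variable oscillation summaries over the trailing window."""
    n0 = int(len(traj.t) * (1 - tail))
    t = traj.t[n0:]
    out = {}
    s = settings or OscillationSettings(tail_fraction=1.0)
    for var in variables:
        x = traj.column(var)[n0:]
        try:
            out[var] = detect_oscillation(t, x, var, s).to_dict()
        except InsufficientDataError as exc:
            out[var] = {"variable": var, "oscillatory": False,
                        "error": str(exc)}
    return out


def write_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, default=float))
    return path
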
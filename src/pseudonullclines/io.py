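"""Bit-stable exports for curves, intersections, trajectories and events.

CSV for anything curve- or time-like (analysis-friendly), JSON for typed
records.  Every file embeds the package version and a hash of the
configuration that produced it; nothing uses an RNG, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .bifurcations import BifurcationEvent
from .dynamics import Trajectory
from .nullclines import Intersection, PlanarCurve, PseudoNullcline

__all__ = ["config_hash", "write_curve_csv", "write_intersections_json",
           "write_trajectory_csv", "write_events_json"]

_FMT = "{:.12g}"


def _f(x) -> str:
    return _FMT.format(float(x))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# pseudonullclines v{__version__} config_hash={h}\n"


def write_curve_csv(path, pnc: PseudoNullcline, curve: PlanarCurve,
                    state_names: tuple[str, ...], config: dict | None = None) -> None:
    """One row per traced point: branch id, input value, module state,
    projected coordinates and residual."""
    lines = [_header(config)]
    lines.append("branch_id,input_value," + ",".join(state_names)
                 + f",proj_{curve.u_label},proj_{curve.v_label},residual\n")
    by_id = {br["branch_id"]: br for br in curve.branches}
    for br in pnc.branches:
        pb = by_id.get(br.branch_id)
        if pb is None:
            continue
        uv = {round(float(a), 15): i for i, a in enumerate(pb["inputs"])}
        for a, s, r in zip(br.inputs, br.states, br.residuals):
            i = uv.get(round(float(a), 15))
            if i is None:
                continue  # point dropped by the projection
            u, v = pb["uv"][i]
            lines.append(",".join([str(br.branch_id), _f(a)]
                                  + [_f(x) for x in s] + [_f(u), _f(v), _f(r)]) + "\n")
    Path(path).write_text("".join(lines))


def _intersection_record(it: Intersection) -> dict:
    return {
        "u": float(it.u), "v": float(it.v),
        "state": [float(x) for x in it.state],
        "residual": float(it.residual),
        "classification": it.classification,
        "stability": it.stability,
        "eigenvalues": [[float(e.real), float(e.imag)] for e in it.eigenvalues],
        "tangent_angle_deg": None if it.angle_deg is None else float(it.angle_deg),
        "converged": bool(it.converged),
        "grazing": bool(it.grazing),
    }


def write_intersections_json(path, intersections: list[Intersection],
                             config: dict | None = None) -> None:
    doc = {
        "package": f"pseudonullclines v{__version__}",
        "config_hash": config_hash(config or {}),
        "intersections": [_intersection_record(i) for i in intersections],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_trajectory_csv(path, traj: Trajectory, config: dict | None = None) -> None:
    lines = [_header(config)]
    cols = ["time"] + list(traj.names)
    if traj.uv is not None:
        cols += ["proj_u", "proj_v"]
    lines.append(",".join(cols) + "\n")
    for i, t in enumerate(traj.t):
        row = [_f(t)] + [_f(x) for x in traj.states[i]]
        if traj.uv is not None:
            row += [_f(traj.uv[i][0]), _f(traj.uv[i][1])]
        lines.append(",".join(row) + "\n")
    Path(path).write_text("".join(lines))


def _event_record(ev: BifurcationEvent) -> dict:
    diag = {}
    for k, v in ev.diagnostics.items():
        if isinstance(v, np.ndarray):
            diag[k] = [[float(e.real), float(e.imag)] for e in np.atleast_1d(v)] \
                if np.iscomplexobj(v) else [float(x) for x in np.atleast_1d(v)]
        elif isinstance(v, (list, tuple)):
            diag[k] = [list(map(float, x)) if isinstance(x, (list, tuple)) else float(x)
                       for x in v]
        elif isinstance(v, (bool, np.bool_)):
            diag[k] = bool(v)
        elif isinstance(v, (int, float, np.floating, np.integer)):
            diag[k] = float(v)
        else:
            diag[k] = str(v)
    return {
        "type": ev.type,
        "parameter": float(ev.parameter),
        "bracket": [float(ev.bracket[0]), float(ev.bracket[1])],
        "state": None if ev.state is None else [float(x) for x in ev.state],
        "boundary": bool(ev.boundary),
        "diagnostics": diag,
    }


def write_events_json(path, events: list[BifurcationEvent],
                      config: dict | None = None) -> None:
    doc = {
        "package": f"pseudonullclines v{__version__}",
        "config_hash": config_hash(config or {}),
        "events": [_event_record(e) for e in events],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
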
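"""Per-model analysis setups: canonical curve geometry, scan parameter,
steady-state finder and default initial conditions.

The *pipeline finder* sources steady-state candidates from the
pseudo-nullcline intersections — the method's own machinery — at scan grid
values, and from warm-started Newton polishing between them (bifurcation
bisection refines thousands of off-grid values; re-tracing curves there would
be wasteful and the warm roots are within Newton's basin).
"""

from __future__ import annotations

import numpy as np

from ..core import ConfigurationError, CoupledSystem
from ..nullclines import NullclineGeometry, SweepConfig, TraceConfig, intersections_of
from .cellcycle import MODIFIED_REGIME, cellcycle_geometry, cellcycle_system
from .mapk22 import (Mapk22Full, lift_to_reduced_coords, mapk22_geometry,
                     mapk22_reduced_system, reduced_initial_state)
from .toys import TOY_NAMES, toy_systems

__all__ = ["analysis_setup", "pipeline_finder"]


def pipeline_finder(geometry_factory, scan_param: str, grid_values=()):
    """Finder for bifurcation scans: pseudo-nullcline intersections at grid
    values, warm-start polishing elsewhere."""
    gv = {round(float(g), 12) for g in grid_values}

    def finder(sysv: CoupledSystem, warm):
        out = [np.asarray(w, float) for w in warm]
        value = round(float(sysv.params[scan_param]), 12)
        if not out or value in gv:
            geo = geometry_factory(sysv.params)
            out += [it.state for it in intersections_of(sysv, geo)]
        return out

    return finder


def _toy_setup(name):
    sys = toy_systems(name)
    b1 = sys.module1.state_bounds[0]
    b2 = sys.module2.state_bounds[0]
    geo = NullclineGeometry(range1=(b2[0], b2[1]), range2=(b1[0], b1[1]),
                            config1=TraceConfig(n_grid=200),
                            config2=TraceConfig(n_grid=200),
                            labels=(sys.coupling.beta_label, sys.coupling.alpha_label))
    return {
        "system": sys,
        "geometry": lambda params: geo,
        "scan_param": "p" if "p" in sys.params else None,
        "observable": sys.module1.state_names[0],
        "initial_state": np.zeros(sys.dim) + 0.1,
        "finder": None,   # brute sweep is fine for the toys
    }


def analysis_setup(name: str, overrides=None, **kw) -> dict:
    """Everything the CLI and the scripts need to analyze a registered model."""
    if name == "cellcycle":
        sys = cellcycle_system(overrides, **kw)
        return {
            "system": sys,
            "geometry": cellcycle_geometry,
            "scan_param": "k_synth",
            "observable": "cdk1a",
            "initial_state": np.array([60.0, 0.0, 0.0, 0.0]),
            "finder": None,  # built per scan via pipeline_finder
            "t_end": 3000.0,
            "modified_regime": dict(MODIFIED_REGIME),
        }
    if name == "mapk22_reduced":
        sys = mapk22_reduced_system(overrides, **kw)
        return {
            "system": sys,
            "geometry": mapk22_geometry,
            "scan_param": "E1tot",
            "observable": "App",
            "initial_state": reduced_initial_state(sys.params),
            "finder": None,
            "t_end": 3000.0,
        }
    if name == "mapk22_full":
        from .mapk22 import mapk22_full_system
        full = mapk22_full_system(overrides, **kw)

        def full_finder_factory(grid_values):
            def finder(sysv: Mapk22Full, warm):
                out = [np.asarray(w, float) for w in warm]
                value = round(float(sysv.params["E1tot"]), 12)
                if not out or value in {round(float(g), 12) for g in grid_values}:
                    red = mapk22_reduced_system(sysv.params.as_dict())
                    for it in intersections_of(red, mapk22_geometry(red.params)):
                        try:
                            out.append(lift_to_reduced_coords(it.state, red.params))
                        except Exception:
                            pass
                return out
            return finder

        return {
            "system": full,
            "geometry": mapk22_geometry,     # geometry of the reduced companion
            "scan_param": "E1tot",
            "observable": "App",
            "initial_state": full.project(full.initial_state17()),
            "finder_factory": full_finder_factory,
            "t_end": 3000.0,
        }
    if name in TOY_NAMES:
        return _toy_setup(name)
    raise ConfigurationError(f"no analysis setup for model {name!r}")
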
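"""Bundled models: case studies and analytic toys, accessible via a registry."""

from __future__ import annotations

from ..core import ConfigurationError
from .cellcycle import cellcycle_system
from .toys import TOY_NAMES, toy_systems

__all__ = ["get_model", "MODEL_NAMES", "cellcycle_system", "toy_systems"]


def _mapk22_full(overrides=None, **kw):
    from .mapk22 import mapk22_full_system
    return mapk22_full_system(overrides, **kw)


def _mapk22_reduced(overrides=None, **kw):
    from .mapk22 import mapk22_reduced_system
    return mapk22_reduced_system(overrides, **kw)


_REGISTRY = {
    "cellcycle": cellcycle_system,
    "mapk22_full": _mapk22_full,
    "mapk22_reduced": _mapk22_reduced,
    **{name: (lambda n: (lambda overrides=None, **kw: toy_systems(n)))(name)
       for name in TOY_NAMES},
}

MODEL_NAMES = tuple(_REGISTRY)


def get_model(name: str, overrides=None, **kw):
    """Instantiate a registered model with optional parameter overrides."""
    if name not in _REGISTRY:
        raise ConfigurationError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    builder = _REGISTRY[name]
    if name in TOY_NAMES:
        sys = builder()
        if overrides or kw:
            sys = sys.with_params(overrides, **kw)
        return sys
    return builder(overrides, **kw)
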
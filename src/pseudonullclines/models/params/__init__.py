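"""Flat key=value parameter files, one per bundled model."""

from __future__ import annotations

from importlib import resources

from ...core import ParameterSet

__all__ = ["load_params"]


def load_params(name: str) -> ParameterSet:
    text = resources.files(__package__).joinpath(f"{name}.txt").read_text()
    values = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = float(val.strip())
    return ParameterSet(values)
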
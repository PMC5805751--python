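"""Access to the bundled toy and synthetic model fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model_file import load_model

NAMES = ("toy_vj", "toy_vdj", "trb_synth", "igh_synth", "igh_shm")


def bundled_path(filename: str) -> Path:
    with resources.as_file(resources.files("repgen") / "data" / filename) as p:
        return Path(p)


def bundled_model(name: str):
    """(RecombModel, hypermutation model or None) for a bundled fixture name."""
    if name not in NAMES:
        raise KeyError(f"unknown bundled model {name!r}; options: {NAMES}")
    return load_model(bundled_path(f"model_{name}.txt"))
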
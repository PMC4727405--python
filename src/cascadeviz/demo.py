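"""Bundled demonstration pathways (synthetic, non-biological skeletons)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .datamodel import Pathway
from .io import read_pathway


def _data_dir() -> Path:
    return Path(str(resources.files("cascadeviz") / "data"))


def list_demo_pathways() -> list[str]:
    return sorted(p.stem for p in _data_dir().glob("*.json"))


def load_demo_pathway(name: str) -> Pathway:
    """Load a bundled pathway by stem name, e.g. ``"rtk_demo"``."""
    path = _data_dir() / f"{name}.json"
    if not path.exists():
        raise FileNotFoundError(
            f"no bundled pathway {name!r}; available: {', '.join(list_demo_pathways())}")
    return read_pathway(path)
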
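"""Loading of the YAML data assets shipped with the package."""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def asset_path(name: str) -> Path:
    return Path(str(resources.files("fopnl.assets").joinpath(name)))


@functools.lru_cache(maxsize=None)
def _load_cached(name: str) -> dict[str, Any]:
    with resources.files("fopnl.assets").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_asset(name_or_path: str | Path | None, default_name: str) -> dict[str, Any]:
    """Load a YAML asset by packaged name (cached) or from an explicit path."""
    if name_or_path is None:
        return _load_cached(default_name)
    p = Path(name_or_path)
    if p.exists():
        with open(p, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return _load_cached(str(name_or_path))
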
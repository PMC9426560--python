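"""Loader for the bundled physicochemical/kinetic constants file."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def load_constants() -> dict:
    """Parse and cache ``data/constants.yaml``."""
    ref = resources.files(__package__) / "data" / "constants.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data.get("version") != 1:
        raise RuntimeError(f"unsupported constants schema version {data.get('version')!r}")
    return data
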
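"""Flat key-value configuration files and output provenance.

Config files are plain text, one ``key = value`` per line, ``#``
comments allowed.  CLI flags override file values.  Every output file
embeds (tool version, seed, config hash) so a run can be traced back to
its exact inputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

from . import __version__

__all__ = ["load_config", "config_hash", "provenance_lines"]


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (strings; callers coerce)."""
    cfg: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def config_hash(config: Mapping[str, object]) -> str:
    """Short stable digest of a configuration mapping."""
    canon = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_lines(seed: int | None, config: Mapping[str, object]) -> list[str]:
    """Comment lines embedded at the top of every output file."""
    return [
        f"vancosim {__version__}",
        f"seed: {seed}",
        f"config_hash: {config_hash(config)}",
    ]
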
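"""Parameter-file handling and provenance records."""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from importlib import resources
from pathlib import Path

from .params import DEFAULT_G, ParameterSet

__all__ = ["load_parameters", "save_parameters", "default_parameter_path",
           "provenance"]

log = logging.getLogger(__name__)


def default_parameter_path() -> Path:
    """Path of the packaged canonical parameter file."""
    return Path(str(resources.files("tregdyn") / "data" / "table1.toml"))


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Read a parameter set from TOML (or JSON, by extension).

    Field names mirror the model notation (``a`` .. ``g``, ``beta``,
    ``gamma``, ``epsilon``, ``N0``, ``lam``, optional ``nhat0``). Unknown
    fields are rejected with a field-level message; a missing ``g`` is
    filled with the default and logged. With no path, the packaged
    canonical set is loaded.
    """
    if path is None:
        path = default_parameter_path()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        with path.open("rb") as fh:
            data = tomllib.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a table of parameters")
    if "g" not in data:
        log.warning("%s: no value for g; using default g=%g", path, DEFAULT_G)
        data["g"] = DEFAULT_G
    try:
        return ParameterSet.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_parameters(p: ParameterSet, path: str | Path) -> Path:
    """Write a parameter set to TOML or JSON (lossless round trip)."""
    path = Path(path)
    data = p.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        lines = [f"{key} = {float(value)!r}" for key, value in data.items()]
        path.write_text("\n".join(lines) + "\n")
    return path


def provenance(p: ParameterSet, **extra) -> dict:
    """Run metadata attached to CSV outputs: version, g used, config hash."""
    from . import __version__

    payload = json.dumps(p.to_dict() | extra, sort_keys=True)
    return {
        "tool": "tregdyn",
        "version": __version__,
        "g": p.g,
        "config_sha1": hashlib.sha1(payload.encode()).hexdigest()[:12],
    } | extra
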
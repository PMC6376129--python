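"""Configuration files and run manifests.

A configuration is a flat YAML (or JSON) document with up to three
sections — ``arena``, ``swim``, ``learning`` — whose keys mirror the
fields of :class:`~watermaze.arena.ArenaConfig`,
:class:`~watermaze.swim.SwimParams` and
:class:`~watermaze.learning.LearningParams`.  Cues may be given either
as cartesian positions or as (bearing, radius) pairs.  Every default is
overridable; unknown keys are rejected by name.

Each CLI run writes a ``manifest.json`` capturing the full configuration
snapshot, the master seed, the package version and a checksum per output
file, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .arena import ArenaConfig, CueSpec, compass_to_xy
from .learning import LearningParams
from .swim import SwimParams

__all__ = [
    "ConfigError",
    "default_config",
    "build_configs",
    "load_config",
    "save_config",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


def _cue_to_dict(cue: CueSpec) -> dict:
    return {
        "cue_id": cue.cue_id,
        "position": [float(cue.position[0]), float(cue.position[1])],
        "salience": cue.salience,
        "brightness_label": cue.brightness_label,
    }


def default_config() -> dict:
    """The full default configuration as a plain dict."""
    arena = ArenaConfig()
    return {
        "arena": {
            "pool_radius": arena.pool_radius,
            "platform_center": list(arena.platform_center),
            "platform_radius": arena.platform_radius,
            "escape_region_radius": arena.escape_region_radius,
            "trial_duration": arena.trial_duration,
            "trials_per_day": arena.trials_per_day,
            "n_days": arena.n_days,
            "start_positions": list(arena.start_positions),
            "probe_start": arena.probe_start,
            "cues": [_cue_to_dict(c) for c in arena.cues],
        },
        "swim": dataclasses.asdict(SwimParams()),
        "learning": dataclasses.asdict(LearningParams()),
    }


def _parse_cue(entry: Mapping[str, Any], index: int) -> CueSpec:
    if "cue_id" not in entry:
        raise ConfigError(f"arena.cues[{index}]: missing key 'cue_id'")
    known = {"cue_id", "position", "bearing", "radius", "salience", "brightness_label"}
    unknown = set(entry) - known
    if unknown:
        raise ConfigError(f"arena.cues[{index}]: unknown keys {sorted(unknown)}")
    if "position" in entry:
        pos = tuple(float(v) for v in entry["position"])
    elif "bearing" in entry and "radius" in entry:
        b = math.radians(float(entry["bearing"]))
        r = float(entry["radius"])
        pos = (r * math.sin(b), r * math.cos(b))
    else:
        raise ConfigError(
            f"arena.cues[{index}]: need 'position' or 'bearing' + 'radius'"
        )
    return CueSpec(
        cue_id=str(entry["cue_id"]),
        position=pos,
        salience=float(entry.get("salience", 0.5)),
        brightness_label=str(entry.get("brightness_label", "")),
    )


def _build_section(cls, section: Mapping[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def build_configs(
    doc: Mapping[str, Any] | None,
) -> tuple[ArenaConfig, SwimParams, LearningParams]:
    """Turn a configuration document into typed parameter objects."""
    doc = dict(doc or {})
    unknown = set(doc) - {"arena", "swim", "learning"}
    if unknown:
        raise ConfigError(f"unknown top-level sections {sorted(unknown)}")

    arena_doc = dict(doc.get("arena", {}))
    cues_doc = arena_doc.pop("cues", None)
    if cues_doc is not None:
        arena_doc["cues"] = tuple(
            _parse_cue(c, i) for i, c in enumerate(cues_doc)
        )
    if "platform_center" in arena_doc:
        arena_doc["platform_center"] = tuple(
            float(v) for v in arena_doc["platform_center"]
        )
    if "start_positions" in arena_doc:
        arena_doc["start_positions"] = tuple(arena_doc["start_positions"])
    arena = _build_section(ArenaConfig, arena_doc, "arena")
    swim = _build_section(SwimParams, dict(doc.get("swim", {})), "swim")
    learning = _build_section(LearningParams, dict(doc.get("learning", {})), "learning")
    return arena, swim, learning


def load_config(path: str | Path) -> tuple[ArenaConfig, SwimParams, LearningParams]:
    """Read a YAML/JSON configuration file (missing sections use defaults)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    doc = yaml.safe_load(text) if text.strip() else {}
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return build_configs(doc)


def save_config(path: str | Path, doc: Mapping[str, Any] | None = None) -> None:
    """Write a configuration document (defaults if none given) as YAML."""
    Path(path).write_text(yaml.safe_dump(doc or default_config(), sort_keys=False))


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    seed: int
    version: str
    config: dict
    outputs: dict  # file name -> sha256 of contents
    timestamp: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int,
    config: Mapping[str, Any],
    files: list[str | Path],
) -> RunManifest:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        seed=int(seed),
        version=__version__,
        config=dict(config),
        outputs={Path(f).name: _sha256(Path(f)) for f in files},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=str)
    )
    return manifest
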
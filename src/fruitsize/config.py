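"""Run configuration: file + CLI merging with strict key checking.

Precedence is CLI flag > config file > built-in default.  Unknown keys in
a config file are errors, not warnings, so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .geometry import RansacConfig
from .imaging import PreprocessConfig
from .pipeline import DEFAULT_ROI_PAD, MeasureOptions

__all__ = ["RunConfig", "load_run_config"]

_SECTION_TYPES = {"preprocess": PreprocessConfig, "ransac": RansacConfig}
_TOP_KEYS = {"preprocess", "ransac", "depth_mode", "focal_mode", "roi_pad", "seed"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings of a measurement run."""

    options: MeasureOptions = dataclasses.field(default_factory=MeasureOptions)
    seed: int = 0

    def resolved(self) -> dict:
        """All settings with defaults materialised (for run logging)."""
        return {
            "preprocess": dataclasses.asdict(self.options.preprocess),
            "ransac": dataclasses.asdict(self.options.ransac),
            "depth_mode": self.options.depth_mode,
            "focal_mode": self.options.focal_mode,
            "roi_pad": self.options.roi_pad,
            "seed": self.seed,
        }


def _build_section(cls: type, data: dict, where: str) -> Any:
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_run_config(
    path: str | Path | None = None,
    *,
    seed: int | None = None,
    **overrides: Any,
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file.

    ``overrides`` accepts the top-level keys (``depth_mode``,
    ``focal_mode``, ``roi_pad``) plus dotted section values such as
    ``ransac={"epsilon": 1.5}``; they take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        data = loaded

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")

    for key, value in overrides.items():
        if value is None:
            continue
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown override {key!r}")
        if key in _SECTION_TYPES:
            merged = dict(data.get(key, {}))
            merged.update(value)
            data[key] = merged
        else:
            data[key] = value

    if seed is not None:
        data["seed"] = seed
    run_seed = int(data.get("seed", 0))

    ransac_data = dict(data.get("ransac", {}))
    ransac_data.setdefault("seed", run_seed)
    options = MeasureOptions(
        preprocess=_build_section(PreprocessConfig, data.get("preprocess", {}), "preprocess"),
        ransac=_build_section(RansacConfig, ransac_data, "ransac"),
        depth_mode=data.get("depth_mode", "nearest"),
        focal_mode=data.get("focal_mode", "mean"),
        roi_pad=int(data.get("roi_pad", DEFAULT_ROI_PAD)),
    )
    if options.depth_mode not in ("nearest", "median3"):
        raise ConfigError(f"unknown depth_mode {options.depth_mode!r}")
    if options.focal_mode not in ("mean", "fx", "fy"):
        raise ConfigError(f"unknown focal_mode {options.focal_mode!r}")
    return RunConfig(options=options, seed=run_seed)
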
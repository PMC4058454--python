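"""Run configuration: every tunable of the pipeline, serializable.

Defaults are the documented study parameters: Gaussian reference with
n = 20 applications of a sigma = 1.0, radius-5 kernel; three Otsu
thresholds; re-partition depth capped at 3; watershed seeds >= 10 px
apart.  A run's exact configuration is written next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


def _default_strategies() -> dict[str, str]:
    from .hierarchy import DEFAULT_STRATEGIES

    return dict(DEFAULT_STRATEGIES)


def _default_stack() -> list[dict]:
    from .blur import DEFAULT_STACK_CONFIG

    return [dict(entry) for entry in DEFAULT_STACK_CONFIG]


@dataclass
class RunConfig:
    # --- ROI stage
    canny_sigma: float = 1.0
    close_radius: int = 3
    erode_radius: int = 2
    min_region_area: int = 150
    # --- reference stack
    reference_stack: list[dict] = field(default_factory=_default_stack)
    # --- partition stage
    k: int = 3
    min_seed_distance: int = 10
    # --- hierarchy stage
    strategies: dict[str, str] = field(default_factory=_default_strategies)
    level_layers: dict[int, str] = field(
        default_factory=lambda: {1: "gauss20", 2: "graymorph", 3: "original"}
    )
    dilate_holes: int = 2
    min_fragment: int = 30
    #: strategy picking: "first" (emit all, take the first for the final
    #: map) or "auto" (heuristic solidity score)
    pick: str = "first"
    # --- classifier stage
    model_path: str | None = None
    train_overlap: float = 0.5
    # --- reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3):
            raise ConfigError("k must be 1, 2 or 3")
        if self.pick not in ("first", "auto"):
            raise ConfigError("pick must be 'first' or 'auto'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["level_layers"] = {str(k): v for k, v in self.level_layers.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "level_layers" in d:
            d["level_layers"] = {int(k): v for k, v in d["level_layers"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
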
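"""Run configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..prioritizer import PrioritizerConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything the umbrella pipeline needs; defaults follow the analysis's
    stated settings (β=0.1, warp=50, 10th percentile, targets 9%/30%)."""

    rows: int = 60
    cols: int = 60
    cell_area: float = 1.0
    n_species: int = 12
    n_landcover_types: int = 5
    natural_fraction: float = 0.6
    patchiness: float = 3.0
    natural_cost: float = 10.0
    human_cost: float = 1.0
    pa_fraction: float = 0.05
    pa_patches: int = 3
    n_presences: int = 30
    noise_sd: float = 0.02
    percentile: float = 10.0
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)
    targets: list[float] = field(default_factory=lambda: [0.09, 0.30])
    interpolation: str = "area"
    seed: int = 0
    out_dir: str = "landprior_run"

    def __post_init__(self) -> None:
        if self.interpolation not in ("area", "log-area"):
            raise ValueError("interpolation must be 'area' or 'log-area'")
        if not 0 <= self.pa_fraction <= 1:
            raise ValueError("pa_fraction must be in [0, 1]")
        for t in self.targets:
            if not 0 <= t <= 1:
                raise ValueError("targets must be fractions in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prioritizer"] = asdict(self.prioritizer)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    prio = data.pop("prioritizer", {})
    if isinstance(prio, PrioritizerConfig):
        prio_cfg = prio
    else:
        prio_cfg = PrioritizerConfig(**prio)
    known = set(RunConfig.__dataclass_fields__) - {"prioritizer"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(prioritizer=prio_cfg, **data)
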
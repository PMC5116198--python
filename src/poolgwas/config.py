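"""Run configuration: defaults, YAML/JSON loading, validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .qc import QCThresholds
from .synthetic import DEFAULT_POOL_SIZES, DEFAULT_SIGMA2_POOL


@dataclass
class PanelConfig:
    n_snps: int = 2000
    maf_low: float = 0.01
    maf_high: float = 0.5


@dataclass
class CohortConfig:
    discovery_cases: int = 412
    discovery_controls: int = 498
    replication_cases: int = 539
    replication_controls: int = 1230


@dataclass
class PoolConfig:
    # (cases, controls, replicate arrays) per pool; defaults are the
    # published three-pool discovery design
    sizes: list[list[int]] = field(
        default_factory=lambda: [list(s) for s in DEFAULT_POOL_SIZES]
    )
    sigma2_pool: float = DEFAULT_SIGMA2_POOL
    contribution_cv: float = 0.02


@dataclass
class ArrayConfig:
    channel_imbalance: float = 1.3
    intensity_scale: float = 2000.0
    noise_cv: float = 0.03
    negative_rate: float = 0.01
    probe_count_jitter: float = 0.1


@dataclass
class AssocConfig:
    sigma2_pool: float | str = "auto"
    gw_alpha: float = 5e-8
    suggestive_alpha: float = 1e-6
    r2_min: float = 0.5
    support_alpha: float = 1e-3


@dataclass
class ValidationConfig:
    validation_alpha: float = 1e-4
    replication_alpha: float = 0.05


@dataclass
class RunConfig:
    """Full pipeline configuration with published-design defaults."""

    seed: int = 0
    panel: PanelConfig = field(default_factory=PanelConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pools: PoolConfig = field(default_factory=PoolConfig)
    arrays: ArrayConfig = field(default_factory=ArrayConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    # planted effects: snp index (into the simulated panel) -> allelic OR
    effects: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, alpha in [
            ("gw_alpha", self.assoc.gw_alpha),
            ("suggestive_alpha", self.assoc.suggestive_alpha),
            ("validation_alpha", self.validation.validation_alpha),
            ("replication_alpha", self.validation.replication_alpha),
            ("var_alpha", self.qc.var_alpha),
        ]:
            if not 0 < alpha < 1:
                raise ValueError(f"{name} must be in (0, 1), got {alpha}")
        if not 0 <= self.qc.neg_max <= 1:
            raise ValueError("neg_max must be in [0, 1]")
        if any(v <= 0 for v in self.effects.values()):
            raise ValueError("planted odds ratios must be > 0")
        if self.panel.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["effects"] = {int(k): float(v) for k, v in self.effects.items()}
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build(cls, data: dict[str, Any], ctx: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {ctx}: {sorted(unknown)}")
    return cls(**data)


_SECTIONS = {
    "panel": PanelConfig,
    "cohort": CohortConfig,
    "pools": PoolConfig,
    "arrays": ArrayConfig,
    "qc": QCThresholds,
    "assoc": AssocConfig,
    "validation": ValidationConfig,
}


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    data = dict(data or {})
    top_known = {"seed", "effects"} | set(_SECTIONS)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "effects" in data:
        kwargs["effects"] = {int(k): float(v) for k, v in (data["effects"] or {}).items()}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, dict(data[name] or {}), name)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected.

    An empty file yields the full default configuration (three pools
    totalling 412 cases / 498 controls).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
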
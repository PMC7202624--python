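"""Pipeline configuration: one flat key-value schema, YAML-serializable.

Defaults match the published protocol where it states values (200 trees,
2 μm merge distance, 30 μm fill diameter); everything else is an explicit,
documented choice.  Every field is embedded in run metadata so each numeric
output is traceable to a config snapshot.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    spacing_um: float = 600.0 / 576.0
    feature_scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    n_trees: int = 200
    decision_threshold: float = 0.5
    merge_distance_um: float = 2.0
    fill_diameter_um: float = 30.0
    diagonal_weighted_skeleton_length: bool = False
    wilcoxon_variant: str = "auto"  # auto | exact | normal
    m_tests: int | None = None  # None: computed from the design
    alpha: float = 0.05
    seed_undersample: int = 0
    seed_forest: int = 0
    seed_phantom: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.spacing_um > 0:
            raise ValidationError("spacing_um must be > 0")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not (0 <= self.decision_threshold <= 1):
            raise ValidationError("decision_threshold must be in [0, 1]")
        if self.merge_distance_um < 0 or self.fill_diameter_um < 0:
            raise ValidationError("distance thresholds must be >= 0")
        if self.wilcoxon_variant not in ("auto", "exact", "normal"):
            raise ValidationError(f"unknown wilcoxon variant {self.wilcoxon_variant!r}")
        self.feature_scales = tuple(float(s) for s in self.feature_scales)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_scales"] = list(self.feature_scales)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        version = data.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValidationError(
                f"config schema version {version} unsupported "
                f"(expected {CONFIG_SCHEMA_VERSION})"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must be a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
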
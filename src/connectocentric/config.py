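"""Analysis configuration: density sweep, test families, seeds, paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .metrics import METRICS


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the study analysis.

    The defaults are the published analysis constants: 20-40% density sweep
    in 1% steps, bilateral piriform ROIs as the primary hypothesis family
    (four tests -> per-test alpha 0.05/4 = 0.0125), 100,000 permutations,
    and a surgery family corrected for 10 comparisons (alpha 0.005).
    """

    density_low: int = 20
    density_high: int = 40
    density_step: int = 1
    metrics: tuple[str, ...] = ("degree", "betweenness")
    primary_nodes: tuple[str, ...] = ("lh_piriform", "rh_piriform")
    surgery_nodes: tuple[str, ...] = ("lh_piriform",)
    surgery_family_size: int = 10
    n_permutations: int = 100_000
    family_alpha: float = 0.05
    seed: int = 0
    matrix_dir: str | None = None
    clinical_table: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "metrics", tuple(self.metrics))
        object.__setattr__(self, "primary_nodes", tuple(self.primary_nodes))
        object.__setattr__(self, "surgery_nodes", tuple(self.surgery_nodes))
        if not set(self.metrics) <= set(METRICS) or not self.metrics:
            raise ValueError(f"metrics must be a non-empty subset of {METRICS}")
        if not (
            1 <= self.density_low <= self.density_high <= 100
            and self.density_step >= 1
        ):
            raise ValueError("invalid density sweep bounds")
        if not 0 < self.family_alpha < 1:
            raise ValueError("family_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(mapping, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        d["primary_nodes"] = list(self.primary_nodes)
        d["surgery_nodes"] = list(self.surgery_nodes)
        return d
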
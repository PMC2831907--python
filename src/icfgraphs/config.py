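"""Pipeline configuration: every tuning constant in one serializable record."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Settings for the full filter -> impute -> bootstrap -> graph pipeline.

    Defaults follow the study design where one was stated (20% missingness
    threshold, m=10 imputations, B=10 bootstrap replicates, 20%-of-ensemble
    summary-edge rule) and the package's documented choices elsewhere
    (alpha=0.05, conditioning sets up to size 3, 499 permutations, 10 chained
    -equations cycles, comparison quantile 0.95, characteristic-edge
    reliability bounds 0.5/0.2).
    """

    missing_threshold: float = 0.2
    m: int = 10
    B: int = 10
    method: str = "logistic"  # or "pmm"
    iterations: int = 10
    pmm_donors: int = 5
    alpha: float = 0.05
    max_cond_size: int = 3
    n_perm: int = 499
    summary_fraction: float = 0.2
    comparison_quantile: float = 0.95
    characteristic_high: float = 0.5
    characteristic_low: float = 0.2
    min_component_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.missing_threshold <= 1.0, "missing_threshold in [0,1]"),
            (self.m >= 1, "m >= 1"),
            (self.B >= 1, "B >= 1"),
            (self.method in ("logistic", "pmm"), "method logistic|pmm"),
            (self.iterations >= 0, "iterations >= 0"),
            (self.pmm_donors >= 1, "pmm_donors >= 1"),
            (0.0 < self.alpha < 1.0, "alpha in (0,1)"),
            (self.max_cond_size >= 0, "max_cond_size >= 0"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0.0 < self.summary_fraction <= 1.0, "summary_fraction in (0,1]"),
            (0.0 < self.comparison_quantile < 1.0, "comparison_quantile in (0,1)"),
            (0.0 <= self.characteristic_low < self.characteristic_high <= 1.0,
             "0 <= low < high <= 1"),
            (self.min_component_size >= 1, "min_component_size >= 1"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid config: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
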
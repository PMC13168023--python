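"""Pipeline configuration: every applied threshold, in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All thresholds of the co-abundance pipeline with their standard
    defaults (prevalence 10%, network FDR 0.05, strength cut 0.2,
    Q-stable alpha 0.05, I2 cut 75%, heterogeneity FDR 0.05, association
    FDR 0.2, Zi 2.5 / Pi 0.62, outlier Z 2.698, core 90% / cloud 10%
    pathway prevalence, 10 robustness replicates)."""

    # inputs (optional when simulate=True)
    abundance_paths: dict[str, str] = field(default_factory=dict)  # stage -> TSV
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    stages: list[str] = field(default_factory=lambda: ["D25", "D120", "D240"])
    simulate: bool = False
    # synthetic-data scale (used when simulate=True)
    n_taxa: int = 150
    n_samples: int = 300
    depth: int = 50_000
    # thresholds
    min_prevalence: float = 0.10
    network_fdr: float = 0.05
    n_permutations: int = 1000
    n_inner: int = 20
    strength_cut: float = 0.2
    alpha_stable: float = 0.05
    i2_cut: float = 75.0
    heterogeneity_fdr: float = 0.05
    association_fdr: float = 0.2
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    outlier_z: float = 2.698
    core_prevalence: float = 0.90
    cloud_prevalence: float = 0.10
    robustness_reps: int = 10
    seed: int = 0

    def __post_init__(self):
        checks = {
            "min_prevalence": (0 < self.min_prevalence <= 1),
            "network_fdr": (0 < self.network_fdr <= 1),
            "strength_cut": (0 <= self.strength_cut < 1),
            "alpha_stable": (0 < self.alpha_stable < 1),
            "i2_cut": (0 <= self.i2_cut <= 100),
            "heterogeneity_fdr": (0 < self.heterogeneity_fdr <= 1),
            "association_fdr": (0 < self.association_fdr <= 1),
            "outlier_z": (self.outlier_z > 0),
            "core_prevalence": (0 < self.core_prevalence <= 1),
            "cloud_prevalence": (0 <= self.cloud_prevalence < self.core_prevalence),
            "robustness_reps": (self.robustness_reps >= 1),
            "n_permutations": (self.n_permutations >= 100),
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config values out of domain: {bad}")
        if not self.simulate and not self.abundance_paths:
            raise ValueError("abundance_paths required unless simulate=True")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
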
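"""Pipeline configuration: validated flat key-value settings."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable pipeline settings with their published defaults.

    One global ``seed`` is fanned out to independent per-stage substreams,
    so stages stay individually reproducible.
    """

    seed: int = 0
    # synthetic study
    n_logs: int = 45
    n_fungi: int = 30
    n_motus: int = 40
    species_effect: float = 1.0
    divergence_within: float = 0.02
    # clustering
    clustering_threshold: float = 0.97
    # community statistics
    kmeans_k: int = 4
    n_permutations: int = 999
    # null model
    ensemble_size: int = 100
    burn_in: int | None = None  # default: 10 x occupied cells
    spacing: int | None = None  # default: 5 x occupied cells
    min_occurrence: int = 3
    z_threshold: float = 1.96
    # network
    affiliation_threshold: float = 0.75
    hub_threshold: int = 10

    def __post_init__(self) -> None:
        if self.n_logs < 4:
            raise ValueError("n_logs must be >= 4")
        if self.n_fungi <= 0 or self.n_motus <= 0:
            raise ValueError("taxon counts must be positive")
        if not 0 < self.clustering_threshold <= 1:
            raise ValueError("clustering_threshold must lie in (0, 1]")
        if not 0 <= self.divergence_within < 1:
            raise ValueError("divergence_within must lie in [0, 1)")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        if self.n_permutations < 1 or self.ensemble_size < 1:
            raise ValueError("permutation and ensemble counts must be >= 1")
        if self.min_occurrence < 1:
            raise ValueError("min_occurrence must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if not 0.5 <= self.affiliation_threshold <= 1:
            raise ValueError("affiliation_threshold must lie in [0.5, 1]")
        if self.hub_threshold < 0:
            raise ValueError("hub_threshold must be non-negative")

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**values)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        if not isinstance(values, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(values)

    def to_dict(self) -> dict:
        return asdict(self)
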
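"""Pipeline configuration: defaults, validation, serialization."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the network/statistics pipeline in one place.

    Defaults follow the study design: 28 density sample points, Silverman
    bandwidth, similarity ``1 - JSD``, sparsity 0.03..0.30 in steps of
    0.01 (28 levels), 100 rewired nulls, 1000 permutations, BH-FDR at
    q = 0.05, AUC across sparsity as the per-subject scalar.
    """

    grid_size: int = 28
    bandwidth: str | float = "silverman"
    similarity_variant: str = "one_minus_jsd"
    grid_policy: str = "pair_union"
    sparsity_min: float = 0.03
    sparsity_max: float = 0.30
    sparsity_step: float = 0.01
    n_null: int = 100
    n_perm: int = 1000
    fdr_q: float = 0.05
    summary_mode: str = "auc"
    swap_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not (0 < self.sparsity_min <= self.sparsity_max <= 1):
            raise ValueError("sparsity range must lie in (0, 1]")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if self.n_null < 0 or self.n_perm < 1:
            raise ValueError("n_null and n_perm must be positive")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.summary_mode not in ("auc", "per-level"):
            raise ValueError("summary_mode must be 'auc' or 'per-level'")
        if isinstance(self.bandwidth, str) and self.bandwidth != "silverman":
            raise ValueError("bandwidth must be 'silverman' or a number")

    @property
    def sparsity_grid(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)
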
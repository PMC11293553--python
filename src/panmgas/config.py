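"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults follow the reference analysis: 10 million read downsizing, effect
size 0.3, Jaccard 0.75, association coverage 0.75, hypergeometric p < 1e-4
with >= 10 associated MSPs, proportionality 0.65 with prevalence > 50
samples, top-100 regional MSPs, 70/30 split, 500 trees.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

logger = logging.getLogger("panmgas")

#: default top-level seed, used (and logged) when the caller provides none
DEFAULT_SEED = 17

__all__ = ["RunConfig", "validate_run_config", "DEFAULT_SEED"]


@dataclass
class RunConfig:
    target_depth: int = 10_000_000
    min_marker_fraction: float = 0.10
    markers_per_msp: int = 100
    es_threshold: float = 0.3
    min_test_prevalence: int = 5
    jaccard_threshold: float = 0.75
    walk_steps: int = 4
    min_representative_species: int = 3
    association_coverage: float = 0.75
    min_cluster_msps: int = 10
    hypergeom_alpha: float = 1e-4
    rho_threshold: float = 0.65
    min_prevalence_samples: int = 50
    top_k_region: int = 100
    top_k_differences: int = 18
    train_fraction: float = 0.70
    n_trees: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        unit = {
            "min_marker_fraction": self.min_marker_fraction,
            "jaccard_threshold": self.jaccard_threshold,
            "association_coverage": self.association_coverage,
            "hypergeom_alpha": self.hypergeom_alpha,
            "train_fraction": self.train_fraction,
        }
        for name, v in unit.items():
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} out of range (0, 1]")
        if not -1 <= self.rho_threshold <= 1:
            raise ValueError(f"rho_threshold={self.rho_threshold} out of [-1, 1]")
        positive = {
            "target_depth": self.target_depth,
            "markers_per_msp": self.markers_per_msp,
            "walk_steps": self.walk_steps,
            "top_k_region": self.top_k_region,
            "top_k_differences": self.top_k_differences,
            "n_trees": self.n_trees,
        }
        for name, v in positive.items():
            if v < 1:
                raise ValueError(f"{name}={v} must be >= 1")
        if self.es_threshold < 0:
            raise ValueError("es_threshold must be >= 0")
        if self.seed is None:
            self.seed = DEFAULT_SEED
            logger.info("no seed supplied; using documented default %d", DEFAULT_SEED)
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_run_config(config: dict | RunConfig | None = None) -> RunConfig:
    """Normalize a (possibly partial) configuration mapping.

    Unknown keys are rejected; missing keys take the reference defaults;
    out-of-range thresholds raise ``ValueError``.
    """
    if config is None:
        config = {}
    if isinstance(config, RunConfig):
        return config
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**config)
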
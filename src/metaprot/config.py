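"""Run configuration: thresholds, seeds and simulation settings.

One structured YAML file drives the whole pipeline; CLI flags override
individual fields.  All stochastic stages draw from a single seed
registry so a fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic-study settings (the generator's study conditions)."""

    n_species: int = 30
    dirichlet_alpha: float = 0.5
    proteins_per_species: int = 10
    shared_peptide_rate: float = 0.05
    depth: int = 3000
    n_mice: int = 12
    diet_effect_sigma: float = 0.9
    group_effect_sigma: float = 0.7
    noise_sigma: float = 0.25
    host_fraction: float = 0.20
    diet_fraction: float = 0.04
    lowq_fraction: float = 0.03
    unbinned_fraction: float = 0.08


@dataclass(frozen=True)
class Thresholds:
    """Quantification thresholds with their documented ranges."""

    fdr: float = 0.05
    biomass_min_unique: int = 2
    abundant_pct: float = 5.0
    identity_merge: float = 0.90
    identity_reference: float = 0.95
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")
        if self.biomass_min_unique < 1:
            raise ValueError("biomass_min_unique must be >= 1")
        if not 0.0 <= self.abundant_pct <= 100.0:
            raise ValueError("abundant_pct outside [0, 100]")
        for name in ("identity_merge", "identity_reference"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} {value} outside (0, 1]")
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError("q_threshold outside [0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs."""

    outdir: str = "run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    permanova_factors: tuple[str, ...] = (
        "protein_source",
        "protein_amount",
        "mouse_group",
        "mouse_age",
    )
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = SyntheticConfig(**raw.pop("synthetic", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        factors = tuple(raw.pop("permanova_factors", cls.permanova_factors))
        return cls(
            synthetic=synthetic,
            thresholds=thresholds,
            permanova_factors=factors,
            **raw,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
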
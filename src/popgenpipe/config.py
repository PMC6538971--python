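"""Pipeline configuration: a validated, YAML-loadable schema.

Unknown keys are rejected so typos fail before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .qc import GenotypeFilterConfig, SiteFilterConfig
from .simulate import DemographyConfig, NoiseConfig


@dataclass
class SimulateStageConfig:
    n1: int = 4
    n2: int = 4
    num_loci: int = 200
    syn_fraction: float = 0.3
    coding_fraction: float = 1.0
    gene_span: int = 10_000


@dataclass
class DemographyStageConfig:
    models: tuple = ("SI", "IM", "AM", "SC")
    #: pipeline-level default kept small for interactive runs; fit_model
    #: itself defaults to the full 50 replicate starts
    n_replicates: int = 6
    grid_size: int = 96
    maxiter: int = 300
    n1_eff: int = 4
    n2_eff: int = 4


@dataclass
class DfeStageConfig:
    enabled: bool = True
    n_grid: int = 64
    n_starts: int = 12


@dataclass
class ComparativeStageConfig:
    ds: float = 0.04
    T_split_years: float = 8.5e6
    life_history_csv: str | None = None
    diversity_csv: str | None = None
    loadings_yaml: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple = ("simulate", "qc", "stats", "sfs", "demography",
                     "dfe", "comparative")
    # default model yields enough polymorphism for a meaningful demo run
    demography_model: DemographyConfig = field(default_factory=lambda: DemographyConfig(
        model_kind="IM", N_anc=10_000.0, nu1=1.0, nu2=1.0, T_split=0.5,
        m12=1.0, m21=1.0, mu=1e-8, L=2_000_000))
    simulate: SimulateStageConfig = field(default_factory=SimulateStageConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    genotype_filters: GenotypeFilterConfig = field(default_factory=GenotypeFilterConfig)
    site_filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    demography_fit: DemographyStageConfig = field(default_factory=DemographyStageConfig)
    dfe: DfeStageConfig = field(default_factory=DfeStageConfig)
    comparative: ComparativeStageConfig = field(default_factory=ComparativeStageConfig)

    def validate(self) -> None:
        self.demography_model.validate()
        self.noise.validate()
        self.genotype_filters.validate()
        self.site_filters.validate()
        known = {"simulate", "qc", "stats", "sfs", "demography", "dfe",
                 "comparative"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "demography_model": DemographyConfig,
    "simulate": SimulateStageConfig,
    "noise": NoiseConfig,
    "genotype_filters": GenotypeFilterConfig,
    "site_filters": SiteFilterConfig,
    "demography_fit": DemographyStageConfig,
    "dfe": DfeStageConfig,
    "comparative": ComparativeStageConfig,
}


def _build_section(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ValueError(f"{path} must be a mapping")
    valid = set(cls.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown keys under {path}: {sorted(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top_valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - top_valid
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "stages":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    config = PipelineConfig(**kwargs)
    config.validate()
    return config
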
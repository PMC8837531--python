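"""Run configuration: YAML loading, validation and audit hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .classify import ClassifierConfig
from .resactivity import ResidualConfig


class ConfigError(ValueError):
    """The run configuration is missing or malformed."""


@dataclass
class GseaConfig:
    metric: str = "log2fc"
    weight: float = 1.0
    n_perm: int = 1000
    seed: int = 7
    exhaustive_limit: int = 10000
    fdr_threshold: float = 0.25

    def __post_init__(self):
        if self.metric not in ("log2fc", "s2n"):
            raise ConfigError(f"unknown GSEA metric {self.metric!r}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigError("fdr_threshold must be in (0, 1]")

    def to_dict(self):
        return asdict(self)


@dataclass
class DEConfig:
    fc_threshold: float = 1.0
    q_threshold: float = 0.05

    def __post_init__(self):
        if self.fc_threshold < 0 or not 0 < self.q_threshold <= 1:
            raise ConfigError("bad DE thresholds")

    def to_dict(self):
        return asdict(self)


@dataclass
class RunConfig:
    """Everything a composed workflow needs, fully serializable."""

    variants: Optional[str] = None
    variant_schema: Optional[str] = None
    expression: Optional[str] = None
    labels: Optional[str] = None
    gene_sets: Optional[str] = None
    chip_genes: Optional[str] = None
    out_prefix: str = "p53mutome_out"
    pseudocount: float = 1.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    residual: ResidualConfig = field(default_factory=ResidualConfig)
    gsea: GseaConfig = field(default_factory=GseaConfig)
    de: DEConfig = field(default_factory=DEConfig)

    def to_dict(self):
        d = asdict(self)
        d["classifier"] = self.classifier.to_dict()
        d["residual"] = self.residual.to_dict()
        d["gsea"] = self.gsea.to_dict()
        d["de"] = self.de.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {"classifier": ClassifierConfig, "residual": ResidualConfig,
                  "gsea": GseaConfig, "de": DEConfig}


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"{path}: configuration must be a non-empty mapping")
    kwargs = {}
    known = set(RunConfig.__dataclass_fields__)
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"{path}: unknown configuration key {key!r}")
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: section {key!r} must be a mapping")
            try:
                value = _SECTION_TYPES[key](**value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: bad section {key!r}: {exc}") from exc
        kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
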
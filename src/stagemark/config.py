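"""Pipeline configuration: one flat record of every tunable setting.

Defaults follow the study design the pipeline implements: sd filter at
1.0, 80:20 stratified split, adjusted-p gate 1e-5, top-15 consensus,
VIF threshold 2.0, 85% cumulative-variance criterion, silhouette search
over k = 2..8, 5-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    filter_threshold: float = 1.0
    split_ratio: float = 0.8
    adjp_threshold: float = 1e-5
    top_n: int = 15
    vif_threshold: float = 2.0
    var_threshold: float = 85.0
    k_min: int = 2
    k_max: int = 8
    folds: int = 5
    seed: int = 0
    input_scale: str = "linear"

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ConfigurationError("split_ratio must lie in (0, 1)")
        if self.filter_threshold <= 0:
            raise ConfigurationError("filter_threshold must be > 0")
        if not 0 < self.adjp_threshold <= 1:
            raise ConfigurationError("adjp_threshold must lie in (0, 1]")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")
        if self.vif_threshold < 1:
            raise ConfigurationError("vif_threshold must be >= 1")
        if not 0 < self.var_threshold <= 100:
            raise ConfigurationError("var_threshold is a percentage in (0, 100]")
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigurationError("need 2 <= k_min <= k_max")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.input_scale not in ("linear", "log2"):
            raise ConfigurationError("input_scale must be 'linear' or 'log2'")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


def _from_mapping(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "n_per_stage" in data:
        data = {**data, "n_per_stage": tuple(data["n_per_stage"])}
    if "library_size_range" in data:
        data = {**data, "library_size_range": tuple(data["library_size_range"])}
    try:
        obj = cls(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    obj.validate()
    return obj


def load_pipeline_config(path) -> PipelineConfig:
    return _from_mapping(PipelineConfig, _read_yaml(path))


def load_cohort_config(path) -> CohortConfig:
    return _from_mapping(CohortConfig, _read_yaml(path))


def _read_yaml(path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of settings")
    return data
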
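"""Run-configuration schemas for the command-line interface.

Configs are hierarchical YAML files validated with pydantic before any
computation; unknown keys are rejected.  Command-line flags override file
values.  Every run writes its fully resolved config next to its outputs so a
run can be reproduced bit-for-bit from that file (with the mock embedder).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import ModelConfig
from .synthetic import SyntheticSpec


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProviderConfig(_StrictModel):
    name: str = "mock"
    dim: int = Field(32, ge=1)
    window: int = Field(1, ge=0)
    version: str = "1"


class GenerateConfig(_StrictModel):
    n_pairs: int = Field(700, ge=1)
    ab_length_range: tuple[int, int] = (55, 65)
    ag_length_range: tuple[int, int] = (75, 90)
    paratope_span: tuple[int, int] = (20, 30)
    epitope_span: tuple[int, int] = (30, 40)
    w_local: float = 0.1
    w_global: float = 0.4
    noise_sd: float = Field(0.2, ge=0.0)
    base_pkd: float = 6.0
    charge_enrichment: float = Field(0.5, ge=0.0, le=1.0)
    hydrophobic_range: tuple[float, float] = (0.2, 0.6)
    seed: int = 0

    def to_spec(self) -> SyntheticSpec:
        return SyntheticSpec(**self.model_dump())


class TrainConfig(_StrictModel):
    variant: str = "full"
    provider: ProviderConfig = ProviderConfig()
    compress_hidden: tuple[int, ...] = ()
    refine_hidden: tuple[int, ...] = ()
    share_compress: bool = False
    num_harmonics: int = Field(2, ge=1)
    l_ab_max: int = Field(256, ge=1)
    l_ag_max: int = Field(96, ge=1)
    gspe_m: int = Field(64, ge=1)
    gspe_q: int = Field(16, ge=1)
    gspe_n_sets: int = Field(8, ge=1)
    basis_seed: int = 0
    head_hidden: tuple[int, ...] = (32, 32)
    compute_dtype: str = "float32"
    spectral_init: bool = True
    lr_schedule: str = "cosine"
    clip_norm: float = Field(5.0, ge=0)
    lr: float = Field(1e-2, gt=0)
    weight_decay: float = Field(1e-3, ge=0)
    batch_size: int = Field(64, ge=1)
    max_epochs: int = Field(200, ge=1)
    patience: int = Field(60, ge=0)
    val_fraction: float = Field(0.15, ge=0.0, lt=1.0)
    group_split: bool = False
    seed: int = 0

    def to_model_config(self) -> ModelConfig:
        fields = {
            k: v for k, v in self.model_dump().items()
            if k not in ("provider", "val_fraction", "group_split")
        }
        return ModelConfig(embed_dim=self.provider.dim, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in fields.items()
            if k != "embed_dim"
        })


def load_yaml_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def dump_resolved_config(config: BaseModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
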
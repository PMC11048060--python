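"""Pipeline configuration (validated) and run manifests.

A single YAML/JSON file drives the whole workflow; pydantic validation turns
schema mistakes into field-level error reports before anything runs.  Every
artifact directory gets a manifest recording the config hash, seed and
checkpoint lineage, which is what makes reruns resumable and artifacts
traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .synthetic import DEFAULT_PREVALENCE

TOOL_VERSION = "0.1.0"


class CorpusSection(BaseModel):
    n_train: int = 200
    n_validation: int = 40
    n_test: int = 40
    k_pathologies: int = Field(6, ge=1)
    image_size: int = 64
    noise_amplitude: float = Field(0.05, ge=0)
    prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))


class ModelSection(BaseModel):
    patch_size: int = 16
    dim: int = 128
    enc_depth: int = Field(2, ge=1)
    enc_heads: int = 4
    dec_layers: int = Field(3, ge=1)
    dec_heads: int = 4
    ffn_hidden: int | None = None
    max_len: int = Field(64, ge=2)
    beam_width: int = Field(4, ge=1)
    n_samples: int = 1
    seed: int = 0


class StageSection(BaseModel):
    epochs: int | None = Field(None, ge=1)
    base_lr: float | None = Field(None, gt=0)
    batch_size: int | None = Field(None, ge=1)
    sample_logit_scale: float = Field(1.0, gt=0)
    image_augment: bool = False
    text_augment: bool = False
    hnm: bool = False
    grad_clip: float = 1.0
    weight_decay: float = 0.01
    reward_embeddings: str = "random"


class RLWeightsSection(BaseModel):
    alpha: float = Field(0.495, ge=0)
    beta: float = Field(0.495, ge=0)
    gamma: float = Field(0.010, ge=0)


class PipelineConfig(BaseModel):
    seed: int = 0
    corpus: CorpusSection = Field(default_factory=CorpusSection)
    model: ModelSection = Field(default_factory=ModelSection)
    nll: StageSection = Field(default_factory=StageSection)
    rl: StageSection = Field(default_factory=StageSection)
    rl_weights: RLWeightsSection = Field(default_factory=RLWeightsSection)

    model_config = {"extra": "forbid"}

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML (or JSON) pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


class RunManifest(BaseModel):
    """Provenance record written next to every produced artifact."""

    config_hash: str
    seed: int
    corpus_path: str
    nll_checkpoint: str | None = None
    rl_checkpoint: str | None = None
    tool_version: str = TOOL_VERSION

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), sort_keys=True, indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls.model_validate(json.loads(Path(path).read_text()))
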
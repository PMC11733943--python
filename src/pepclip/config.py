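"""Structured run configuration (schema-validated; unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ModelConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureSection(_Strict):
    n_peptides: int = 100
    length_min: int = 5
    length_max: int = 40
    positive_fraction: float = Field(default=0.15065, gt=0.0, lt=1.0)
    label_rule: str = "hydrophobic_fraction"


class GraphSection(_Strict):
    cutoff: float = Field(default=6.0, gt=0.0)


class PrepSection(_Strict):
    dedup_mode: str = "conflict_drop"
    paper_order: bool = False  # oversample before the split (replication mode)
    split_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    stratify: bool = True

    @field_validator("dedup_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("conflict_drop", "same_label_collapse"):
            raise ValueError(f"unknown dedup_mode {v!r}")
        return v


class EncoderSection(_Strict):
    max_length: int = 200
    text_width: int = 64
    text_layers: int = 2
    text_heads: int = 4
    text_ffn_mult: int = 2
    text_pooling: str = "first_token"
    graph_hidden_width: int = 64
    graph_conv_layers: int = 2
    graph_mlp_widths: list[int] = [64]
    graph_out_width: int = 64
    graph_center_coords: bool = True
    graph_append_bias_feature: bool = False
    latent_width: int = 128
    dropout_rate: float = Field(default=0.1, ge=0.0, lt=1.0)

    def to_model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(
            max_length=self.max_length,
            text_width=self.text_width,
            text_layers=self.text_layers,
            text_heads=self.text_heads,
            text_ffn_mult=self.text_ffn_mult,
            text_pooling=self.text_pooling,
            graph_in_width=10 + int(self.graph_append_bias_feature),
            graph_hidden_width=self.graph_hidden_width,
            graph_conv_layers=self.graph_conv_layers,
            graph_mlp_widths=tuple(self.graph_mlp_widths),
            graph_out_width=self.graph_out_width,
            graph_center_coords=self.graph_center_coords,
            graph_append_bias_feature=self.graph_append_bias_feature,
            latent_width=self.latent_width,
            dropout_rate=self.dropout_rate,
            seed=seed,
        )


class StageSection(_Strict):
    epochs: int = Field(default=10, ge=1)
    batch_size: int = Field(default=20, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0.0)
    weight_decay: float = 0.01
    plateau_factor: float = Field(default=0.4, gt=0.0, lt=1.0)
    patience_epochs: int = 5
    tau: float = Field(default=0.07, gt=0.0)
    aux_bce_weight: float = Field(default=0.0, ge=0.0)


class EvalSection(_Strict):
    threshold: float = 0.5
    tsne_dims: int = 2
    tsne_perplexity: float = 10.0


class RunConfig(_Strict):
    out_dir: str = "pepclip_run"
    seed: int = 0
    fixtures: FixtureSection = Field(default_factory=FixtureSection)
    graph: GraphSection = Field(default_factory=GraphSection)
    prep: PrepSection = Field(default_factory=PrepSection)
    encoders: EncoderSection = Field(default_factory=EncoderSection)
    pretrain_text: StageSection = Field(default_factory=StageSection)
    pretrain_graph: StageSection = Field(default_factory=StageSection)
    align: StageSection = Field(
        default_factory=lambda: StageSection(
            epochs=100, learning_rate=6.0e-5, batch_size=20
        )
    )
    eval: EvalSection = Field(default_factory=EvalSection)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)
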
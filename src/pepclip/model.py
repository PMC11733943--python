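"""The two-encoder model bundle used across pretraining, alignment and
inference: a transformer text encoder and a graph encoder, each with a
binary classification head, plus one projection head per modality
mapping into the shared latent space.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .codec import load_vocab, tokenize_for_lm
from .nn import ClassifierHead, GraphEncoder, Module, ProjectionHead, TextEncoder

__all__ = ["ModelConfig", "PepClipModel"]


@dataclass
class ModelConfig:
    """Desk-scale defaults; every size is overridable up to larger scale."""

    max_length: int = 200
    text_width: int = 128
    text_layers: int = 2
    text_heads: int = 4
    text_ffn_mult: int = 2
    text_pooling: str = "first_token"
    graph_in_width: int = 10
    graph_hidden_width: int = 64
    graph_conv_layers: int = 2
    graph_mlp_widths: tuple[int, ...] = (64,)
    graph_out_width: int = 64
    graph_center_coords: bool = True
    graph_append_bias_feature: bool = False
    latent_width: int = 128
    dropout_rate: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["graph_mlp_widths"] = list(self.graph_mlp_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["graph_mlp_widths"] = tuple(d.get("graph_mlp_widths", (64,)))
        return cls(**d)


class PepClipModel(Module):
    def __init__(self, config: ModelConfig | None = None, vocab: dict | None = None):
        self.config = config = config or ModelConfig()
        self._vocab = vocab or load_vocab()
        base = config.seed
        self.text_encoder = TextEncoder(
            vocab_size=max(self._vocab.values()) + 1,
            max_length=config.max_length,
            width=config.text_width,
            n_layers=config.text_layers,
            n_heads=config.text_heads,
            ffn_mult=config.text_ffn_mult,
            pooling=config.text_pooling,
            seed=base,
        )
        self.graph_encoder = GraphEncoder(
            in_width=config.graph_in_width,
            hidden_width=config.graph_hidden_width,
            n_conv_layers=config.graph_conv_layers,
            mlp_widths=config.graph_mlp_widths,
            out_width=config.graph_out_width,
            center_coords=config.graph_center_coords,
            append_bias_feature=config.graph_append_bias_feature,
            seed=base + 1,
        )
        self.text_proj = ProjectionHead(
            config.text_width, config.latent_width, config.dropout_rate, seed=base + 2
        )
        self.graph_proj = ProjectionHead(
            config.graph_out_width, config.latent_width, config.dropout_rate, seed=base + 3
        )
        self.text_head = ClassifierHead(config.text_width, seed=base + 4)
        self.graph_head = ClassifierHead(config.graph_out_width, seed=base + 5)

    # the dataclass and vocab are config, not parameters
    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {}
        for name in (
            "text_encoder",
            "graph_encoder",
            "text_proj",
            "graph_proj",
            "text_head",
            "graph_head",
        ):
            out.update(getattr(self, name).named_parameters(f"{prefix}{name}."))
        return out

    def components(self) -> dict[str, Module]:
        return {
            "text_encoder": self.text_encoder,
            "graph_encoder": self.graph_encoder,
            "text_proj": self.text_proj,
            "graph_proj": self.graph_proj,
            "text_head": self.text_head,
            "graph_head": self.graph_head,
        }

    def tokenize_batch(self, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Tokenize to the shortest common padded length (plus specials)."""
        width = min(max(len(s) for s in sequences) + 2, self.config.max_length)
        toks = [tokenize_for_lm(s, width, self._vocab) for s in sequences]
        ids = np.array([t.token_ids for t in toks], dtype=int)
        mask = np.array([t.attention_mask for t in toks], dtype=np.float64)
        return ids, mask

    def encode_text(self, sequences: list[str]) -> Tensor:
        ids, mask = self.tokenize_batch(sequences)
        return self.text_encoder(ids, mask)

    def text_probability(self, sequences: list[str]) -> np.ndarray:
        """Sequence-only inference path: tokenize -> encode -> classify."""
        with no_grad():
            return self.text_head(self.encode_text(sequences)).data.reshape(-1)
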
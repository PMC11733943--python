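"""Neural building blocks: transformer text encoder, neighborhood-mean
graph convolution encoder, projection heads and classifier heads.

All parameters live in ``Module`` subclasses as named float64 tensors so
checkpoints and freeze masks can address them by dotted path.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, stack

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "TextEncoder",
    "SAGEConv",
    "GraphEncoder",
    "ProjectionHead",
    "ClassifierHead",
]


class Module:
    """Lightweight parameter container with dotted-path addressing."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Tensor):
                out[name] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(f"{name}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{name}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=np.float64, copy=True)

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        self.weight = _param(rng, in_width, out_width)
        self.bias = Tensor(np.zeros(out_width), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(width), requires_grad=True)
        self.bias = Tensor(np.zeros(width), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self._eps) ** 0.5 * self.gain + self.bias


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


class MultiHeadAttention(Module):
    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        if width % n_heads:
            raise ValueError("model width must be divisible by the head count")
        self.wq = Linear(width, width, rng)
        self.wk = Linear(width, width, rng)
        self.wv = Linear(width, width, rng)
        self.wo = Linear(width, width, rng)
        self._heads = n_heads
        self._dh = width // n_heads

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b, length, width = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, length, self._heads, self._dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self._dh)
        neg = (1.0 - mask)[:, None, None, :] * -1e9  # block padded keys
        attn = (scores + Tensor(neg)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, width)
        return self.wo(ctx)


class TransformerBlock(Module):
    def __init__(self, width: int, n_heads: int, ffn_mult: int, rng):
        self.attn = MultiHeadAttention(width, n_heads, rng)
        self.norm1 = LayerNorm(width)
        self.ff1 = Linear(width, ffn_mult * width, rng)
        self.ff2 = Linear(ffn_mult * width, width, rng)
        self.norm2 = LayerNorm(width)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.attn(x, mask))
        return self.norm2(x + self.ff2(self.ff1(x).gelu()))


class TextEncoder(Module):
    """Masked transformer encoder over tokenized peptide sequences.

    Pooling is either the first-token (classification-token) state or the
    mask-weighted mean over real tokens; both ignore padding positions.
    """

    def __init__(
        self,
        vocab_size: int,
        max_length: int,
        width: int = 128,
        n_layers: int = 2,
        n_heads: int = 4,
        ffn_mult: int = 2,
        pooling: str = "first_token",
        seed: int = 0,
    ):
        if pooling not in ("first_token", "mean"):
            raise ValueError(f"unknown pooling {pooling!r}")
        rng = np.random.default_rng(seed)
        self.tok_emb = _param(rng, vocab_size, width, scale=0.02)
        self.pos_emb = _param(rng, max_length, width, scale=0.02)
        self.blocks = [
            TransformerBlock(width, n_heads, ffn_mult, rng) for _ in range(n_layers)
        ]
        self._pooling = pooling
        self.width = width
        self.max_length = max_length

    def __call__(self, token_ids: np.ndarray, mask: np.ndarray) -> Tensor:
        token_ids = np.atleast_2d(token_ids)
        mask = np.atleast_2d(np.asarray(mask, dtype=np.float64))
        if token_ids.shape[1] > self.max_length:
            raise ValueError(
                f"sequence length {token_ids.shape[1]} exceeds max_length {self.max_length}"
            )
        x = self.tok_emb.take_rows(token_ids) + self.pos_emb[: token_ids.shape[1]]
        for block in self.blocks:
            x = block(x, mask)
        if self._pooling == "first_token":
            return x[:, 0, :]
        weights = mask / mask.sum(axis=1, keepdims=True)
        return (x * Tensor(weights[:, :, None])).sum(axis=1)


class SAGEConv(Module):
    """One neighborhood-aggregation step: a learned affine map of each
    node's own features plus a learned affine map of the arithmetic mean
    of its neighbors' features, followed by a rectifier.

    An isolated node has a zero neighbor-mean, so only the self term
    (plus bias) contributes.
    """

    def __init__(self, in_width: int, out_width: int, rng):
        self.w_self = _param(rng, in_width, out_width)
        self.w_neigh = _param(rng, in_width, out_width)
        self.bias = Tensor(np.zeros(out_width), requires_grad=True)

    def __call__(self, x: Tensor, mean_adj: np.ndarray) -> Tensor:
        return (x @ self.w_self + Tensor(mean_adj) @ x @ self.w_neigh + self.bias).relu()


def mean_adjacency(n_nodes: int, edges: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency so that ``A @ X`` is the neighbor mean."""
    adj = np.zeros((n_nodes, n_nodes))
    if len(edges):
        e = np.asarray(edges)
        adj[e[:, 0], e[:, 1]] = 1.0
        adj[e[:, 1], e[:, 0]] = 1.0
    deg = adj.sum(axis=1, keepdims=True)
    return np.divide(adj, deg, out=np.zeros_like(adj), where=deg > 0)


# fixed per-feature divisors keep heterogeneous node features at O(1) scale
_FEATURE_SCALE = np.array([10.0, 10.0, 10.0, 10.0, 20.0, 1.0, 1.0, 50.0, 10.0, 50.0])


class GraphEncoder(Module):
    """Stack of mean-aggregation graph convolutions, mean readout over
    nodes, then a fully connected network with rectifier activations and
    a final sigmoid-bounded layer producing the graph-level embedding.

    Coordinates are centered at the structure centroid before encoding
    (``center_coords``), which makes the embedding invariant to rigid
    translation of the input structure.
    """

    def __init__(
        self,
        in_width: int = 10,
        hidden_width: int = 64,
        n_conv_layers: int = 2,
        mlp_widths: tuple[int, ...] = (64,),
        out_width: int = 64,
        center_coords: bool = True,
        append_bias_feature: bool = False,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        if append_bias_feature:
            in_width += 1
        widths = [in_width] + [hidden_width] * n_conv_layers
        self.convs = [
            SAGEConv(widths[i], widths[i + 1], rng) for i in range(n_conv_layers)
        ]
        dims = [hidden_width, *mlp_widths, out_width]
        self.mlp = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self._center = center_coords
        self._bias_feature = append_bias_feature
        self.width = out_width

    def prepare_features(self, node_features: np.ndarray) -> np.ndarray:
        x = np.asarray(node_features, dtype=np.float64).copy()
        if self._center:
            x[:, :3] -= x[:, :3].mean(axis=0)
        x /= _FEATURE_SCALE[: x.shape[1]]
        if self._bias_feature:
            x = np.hstack([x, np.ones((x.shape[0], 1))])
        return x

    def __call__(self, node_features: np.ndarray, edges: np.ndarray) -> Tensor:
        if len(node_features) == 0:
            raise ValueError("cannot encode an empty graph")
        x = Tensor(self.prepare_features(node_features))
        mean_adj = mean_adjacency(len(node_features), edges)
        for conv in self.convs:
            x = conv(x, mean_adj)
        h = x.mean(axis=0)
        for layer in self.mlp[:-1]:
            h = layer(h).relu()
        return self.mlp[-1](h).sigmoid()

    def encode_batch(self, graphs: list[tuple[np.ndarray, np.ndarray]]) -> Tensor:
        return stack([self(x, e) for x, e in graphs], axis=0)


class ProjectionHead(Module):
    """Maps an encoder output into the shared latent space.

    linear -> GELU -> linear -> dropout -> residual add of the first
    linear's output -> layer normalization.  Deterministic when no rng is
    supplied (evaluation mode).
    """

    def __init__(
        self,
        in_width: int,
        latent_width: int = 128,
        dropout_rate: float = 0.1,
        seed: int = 0,
    ):
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        rng = np.random.default_rng(seed)
        self.proj = Linear(in_width, latent_width, rng)
        self.dense = Linear(latent_width, latent_width, rng)
        self.norm = LayerNorm(latent_width)
        self._rate = dropout_rate
        self.width = latent_width

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        projected = self.proj(x)
        h = _dropout(self.dense(projected.gelu()), self._rate, rng)
        return self.norm(h + projected)


class ClassifierHead(Module):
    """Affine map plus sigmoid: embedding -> probability in (0, 1)."""

    def __init__(self, in_width: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.linear = Linear(in_width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.linear(x).sigmoid()
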
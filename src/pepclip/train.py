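"""Two-stage training.

Stage 1 pretrains each encoder with its binary classification head on
labeled peptides (binary cross-entropy, AdamW).  Stage 2 aligns the two
modalities in the shared latent space with the symmetric contrastive
loss: the graph encoder is frozen, and only the text encoder and the two
projection heads receive updates.  A reduce-on-plateau scheduler lowers
the learning rate by a fixed factor after a patience window without
improvement of the monitored (training) loss.

All randomness — batch order, oversampling, dropout — derives from the
single config seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .contrastive import LatentBatch, clip_loss
from .model import ModelConfig, PepClipModel
from .nn import Module
from .pdb_graph import PeptideGraph
from .prep import LabeledSequence

__all__ = [
    "TrainConfig",
    "TrainState",
    "AdamW",
    "PlateauScheduler",
    "pretrain",
    "align",
    "checkpoint_save",
    "checkpoint_load",
]

CHECKPOINT_VERSION = "pepclip-checkpoint-1"


@dataclass
class TrainConfig:
    stage: str = "pretrain_text"  # pretrain_text | pretrain_graph | align
    epochs: int = 50
    batch_size: int = 20
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    plateau_factor: float = 0.4
    patience_epochs: int = 5
    tau: float = 0.07
    aux_bce_weight: float = 0.0  # optional classification term during align
    seed: int = 0
    log_every: int = 0  # steps between stdout lines; 0 = silent

    def __post_init__(self):
        if self.stage not in ("pretrain_text", "pretrain_graph", "align"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.stage == "align" and self.batch_size < 2:
            raise ValueError("contrastive alignment needs batch_size >= 2")

    @classmethod
    def for_align(cls, **overrides) -> "TrainConfig":
        """Alignment defaults: 100 epochs, lr 6.0e-5, batch 20, plateau
        factor 0.4 with 5-epoch patience."""
        base = dict(
            stage="align", epochs=100, batch_size=20, learning_rate=6.0e-5
        )
        base.update(overrides)
        return cls(**base)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = dict(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )

    def state_dict(self) -> dict:
        return {
            "lr": self.lr,
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state_dict(self, state: dict):
        self.lr = float(state["lr"])
        self.t = int(state["t"])
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}


@dataclass
class PlateauScheduler:
    """Multiply the learning rate by ``factor`` after ``patience``
    consecutive epochs without improvement of the monitored loss."""

    optimizer: AdamW
    factor: float = 0.4
    patience: int = 5
    best: float = float("inf")
    bad_epochs: int = 0

    def step(self, monitored_loss: float) -> float:
        if monitored_loss < self.best - 1e-12:
            self.best = monitored_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0
        return self.optimizer.lr


@dataclass
class TrainState:
    model: PepClipModel
    optimizer: AdamW
    scheduler: PlateauScheduler
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    epoch: int = 0
    step: int = 0


def _bce(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Binary cross-entropy with probability clamping for stability."""
    eps = 1e-12
    y = Tensor(np.asarray(labels, dtype=np.float64).reshape(probs.shape))
    return -(
        y * (probs + eps).log() + (1.0 - y) * (1.0 - probs + eps).log()
    ).mean()


def _graph_input(graph: PeptideGraph) -> tuple[np.ndarray, np.ndarray]:
    return graph.node_features(), graph.edges


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        chunk = order[start : start + batch_size]
        if len(chunk):
            yield chunk


def _dedup_batches(
    records: list[LabeledSequence], batch_size: int, rng: np.random.Generator
):
    """Batches that never contain the same sequence twice (duplicates can
    survive oversampling; inside one contrastive batch they would make the
    one-to-one targets ill-posed)."""
    queue = [records[i] for i in rng.permutation(len(records))]
    while queue:
        batch: list[LabeledSequence] = []
        seen: set[str] = set()
        leftover: list[LabeledSequence] = []
        for r in queue:
            if len(batch) < batch_size and r.sequence not in seen:
                batch.append(r)
                seen.add(r.sequence)
            else:
                leftover.append(r)
        queue = leftover
        if len(batch) >= 2:
            yield batch


def pretrain(
    encoder_kind: str,
    records: list[LabeledSequence],
    cfg: TrainConfig,
    model: PepClipModel | None = None,
    graphs: dict[str, PeptideGraph] | None = None,
) -> TrainState:
    """Stage 1: train one encoder plus its classification head on binary
    labels with binary cross-entropy and AdamW."""
    if encoder_kind not in ("text", "graph"):
        raise ValueError(f"unknown encoder kind {encoder_kind!r}")
    if not records:
        raise ValueError("no training records")
    labels = {r.label for r in records}
    if len(labels) < 2:
        warnings.warn("training stream contains a single class", stacklevel=2)
    if encoder_kind == "graph":
        if graphs is None:
            raise ValueError("graph pretraining requires a graphs mapping")
        missing = [r.id for r in records if r.id not in graphs]
        if missing:
            raise ValueError(f"missing structures for ids: {missing[:10]}")

    model = model or PepClipModel(ModelConfig(seed=cfg.seed))
    if encoder_kind == "text":
        trainable = {
            **model.text_encoder.named_parameters("text_encoder."),
            **model.text_head.named_parameters("text_head."),
        }
    else:
        trainable = {
            **model.graph_encoder.named_parameters("graph_encoder."),
            **model.graph_head.named_parameters("graph_head."),
        }
    opt = AdamW(trainable, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(opt, cfg.plateau_factor, cfg.patience_epochs)
    state = TrainState(model, opt, sched, cfg)
    rng = np.random.default_rng(cfg.seed)

    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(len(records), cfg.batch_size, rng):
            batch = [records[i] for i in idx]
            y = np.array([r.label for r in batch], dtype=np.float64)
            if encoder_kind == "text":
                probs = model.text_head(model.encode_text([r.sequence for r in batch]))
            else:
                embs = stack(
                    [model.graph_encoder(*_graph_input(graphs[r.id])) for r in batch]
                )
                probs = model.graph_head(embs)
            loss = _bce(probs, y.reshape(-1, 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            state.step += 1
            if cfg.log_every and state.step % cfg.log_every == 0:
                print(f"step {state.step} epoch {epoch} loss {losses[-1]:.5f}")
        epoch_loss = float(np.mean(losses))
        lr = sched.step(epoch_loss)
        state.epoch = epoch + 1
        state.history.append({"epoch": epoch + 1, "loss": epoch_loss, "lr": lr})
    return state


def align(
    text_state: TrainState,
    graph_state: TrainState,
    records: list[LabeledSequence],
    graphs: dict[str, PeptideGraph],
    cfg: TrainConfig | None = None,
) -> TrainState:
    """Stage 2: contrastive alignment in the shared latent space.

    The graph encoder's weights are frozen (bit-identical before and
    after); the text encoder and both projection heads are updated.
    ``text_state`` and ``graph_state`` may share one model object, or the
    graph components are copied across from ``graph_state``.
    """
    cfg = cfg or TrainConfig.for_align()
    if cfg.stage != "align":
        raise ValueError("align() requires an align-stage config")
    missing = [r.id for r in records if r.id not in graphs]
    if missing:
        raise ValueError(f"missing structures for ids: {missing[:10]}")

    model = text_state.model
    if graph_state.model is not model:
        model.graph_encoder.load_state_dict(graph_state.model.graph_encoder.state_dict())
        model.graph_head.load_state_dict(graph_state.model.graph_head.state_dict())

    model.graph_encoder.set_requires_grad(False)  # the frozen modality
    trainable = {
        **model.text_encoder.named_parameters("text_encoder."),
        **model.text_proj.named_parameters("text_proj."),
        **model.graph_proj.named_parameters("graph_proj."),
    }
    opt = AdamW(trainable, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(opt, cfg.plateau_factor, cfg.patience_epochs)
    state = TrainState(model, opt, sched, cfg)
    rng = np.random.default_rng(cfg.seed)

    try:
        for epoch in range(cfg.epochs):
            losses = []
            for batch in _dedup_batches(records, cfg.batch_size, rng):
                t_emb = model.encode_text([r.sequence for r in batch])
                t_lat = model.text_proj(t_emb, rng)
                g_emb = stack(
                    [model.graph_encoder(*_graph_input(graphs[r.id])) for r in batch]
                )
                g_lat = model.graph_proj(g_emb, rng)
                loss = clip_loss(
                    LatentBatch(G=g_lat, T=t_lat, ids=[r.id for r in batch]), cfg.tau
                )
                if cfg.aux_bce_weight > 0.0:
                    y = np.array([r.label for r in batch], dtype=np.float64)
                    loss = loss + cfg.aux_bce_weight * _bce(
                        model.text_head(t_emb), y.reshape(-1, 1)
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                state.step += 1
                if cfg.log_every and state.step % cfg.log_every == 0:
                    print(f"step {state.step} epoch {epoch} loss {losses[-1]:.5f}")
            epoch_loss = float(np.mean(losses))
            lr = sched.step(epoch_loss)
            state.epoch = epoch + 1
            state.history.append({"epoch": epoch + 1, "loss": epoch_loss, "lr": lr})
    finally:
        model.graph_encoder.set_requires_grad(True)
    return state


def checkpoint_save(state: TrainState, path) -> None:
    """Serialize model parameters, optimizer state and training history to
    a single versioned archive (exact float64 round trip)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": state.model.config.to_dict(),
        "train_config": vars(state.config),
        "history": state.history,
        "epoch": state.epoch,
        "step": state.step,
        "scheduler": {
            "factor": state.scheduler.factor,
            "patience": state.scheduler.patience,
            "best": state.scheduler.best,
            "bad_epochs": state.scheduler.bad_epochs,
        },
        "trainable": sorted(state.optimizer.params.keys()),
    }
    arrays = {f"param::{k}": v for k, v in state.model.state_dict().items()}
    arrays.update({f"opt.m::{k}": v for k, v in state.optimizer.m.items()})
    arrays.update({f"opt.v::{k}": v for k, v in state.optimizer.v.items()})
    arrays["opt.t"] = np.array(state.optimizer.t)
    arrays["opt.lr"] = np.array(state.optimizer.lr)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def checkpoint_load(path) -> TrainState:
    try:
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(archive["meta_json"].tobytes()).decode())
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise ValueError(f"unreadable or truncated checkpoint at {path}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')!r} does not match "
            f"expected {CHECKPOINT_VERSION!r}"
        )
    model = PepClipModel(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(
        {k[len("param::") :]: archive[k] for k in archive.files if k.startswith("param::")}
    )
    cfg = TrainConfig(**meta["train_config"])
    params = model.named_parameters()
    trainable = {k: params[k] for k in meta["trainable"]}
    opt = AdamW(trainable, lr=float(archive["opt.lr"]), weight_decay=cfg.weight_decay)
    opt.t = int(archive["opt.t"])
    opt.m = {
        k[len("opt.m::") :]: archive[k] for k in archive.files if k.startswith("opt.m::")
    }
    opt.v = {
        k[len("opt.v::") :]: archive[k] for k in archive.files if k.startswith("opt.v::")
    }
    sched = PlateauScheduler(
        opt,
        meta["scheduler"]["factor"],
        meta["scheduler"]["patience"],
        meta["scheduler"]["best"],
        meta["scheduler"]["bad_epochs"],
    )
    return TrainState(
        model=model,
        optimizer=opt,
        scheduler=sched,
        config=cfg,
        history=meta["history"],
        epoch=meta["epoch"],
        step=meta["step"],
    )
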
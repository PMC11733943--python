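"""End-to-end orchestration: fixtures -> graphs -> prep -> pretrain both
encoders -> contrastive alignment -> sequence-only evaluation.

Every stage derives its seed from the single run seed by a fixed offset,
artifacts are append-only inside the run directory, and a manifest
records every path written.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import fixtures as fx
from . import pdb_graph, prep
from .config import RunConfig
from .infer import evaluate, predict
from .model import PepClipModel
from .prep import LabeledSequence
from .train import TrainConfig, align, checkpoint_save, pretrain

__all__ = ["run_pipeline", "load_graphs", "prepare_records"]

# fixed per-stage seed offsets keep the whole pipeline reproducible
SEED_OFFSETS = {
    "fixtures": 0,
    "prep": 1,
    "pretrain_text": 2,
    "pretrain_graph": 3,
    "align": 4,
    "eval": 5,
}


def stage_seed(run_seed: int, stage: str) -> int:
    return (run_seed * 10 + SEED_OFFSETS[stage]) % (2**31 - 1)


def load_graphs(
    records: list[LabeledSequence], base_dir, cutoff: float = 6.0
) -> dict[str, pdb_graph.PeptideGraph]:
    """Build one peptide graph per record from its structure_ref path."""
    base = Path(base_dir)
    graphs = {}
    missing = [r.id for r in records if not r.structure_ref]
    if missing:
        raise ValueError(f"records without structure_ref: {missing[:10]}")
    for r in records:
        text = (base / r.structure_ref).read_text()
        graphs[r.id] = pdb_graph.graph_from_pdb(text, cutoff=cutoff, peptide_id=r.id)
    return graphs


def prepare_records(
    records: list[LabeledSequence], cfg: RunConfig, seed: int
) -> tuple[list[LabeledSequence], list[LabeledSequence], list[LabeledSequence]]:
    """Dedup, split and balance.

    Returns (train_balanced, train_pairs, test).  Default order splits
    first and oversamples only the training split; ``paper_order``
    oversamples the whole corpus before splitting (replication mode, which
    leaks duplicated minority records across the split).
    """
    records = prep.resolve_duplicates(records, cfg.prep.dedup_mode)
    if cfg.prep.paper_order:
        balanced = prep.oversample_balance(records, seed=seed)
        split = prep.split_train_test(
            balanced, cfg.prep.split_fraction, seed=seed, stratify=cfg.prep.stratify
        )
        return split.train, split.train, split.test
    split = prep.split_train_test(
        records, cfg.prep.split_fraction, seed=seed, stratify=cfg.prep.stratify
    )
    train_balanced = prep.oversample_balance(split.train, seed=seed)
    return train_balanced, split.train, split.test


def _stage_cfg(section, stage: str, seed: int) -> TrainConfig:
    return TrainConfig(
        stage=stage,
        epochs=section.epochs,
        batch_size=section.batch_size,
        learning_rate=section.learning_rate,
        weight_decay=section.weight_decay,
        plateau_factor=section.plateau_factor,
        patience_epochs=section.patience_epochs,
        tau=section.tau,
        aux_bce_weight=section.aux_bce_weight,
        seed=seed,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out), "seed": cfg.seed, "artifacts": {}}

    # 1. synthetic corpus
    spec = fx.FixtureSpec(
        n_peptides=cfg.fixtures.n_peptides,
        length_range=(cfg.fixtures.length_min, cfg.fixtures.length_max),
        positive_fraction=cfg.fixtures.positive_fraction,
        label_rule=cfg.fixtures.label_rule,
        seed=stage_seed(cfg.seed, "fixtures"),
    )
    corpus_dir = out / "corpus"
    fx.generate_corpus(spec, corpus_dir)
    manifest["artifacts"]["corpus"] = str(corpus_dir)
    records = prep.read_labels_csv(corpus_dir / "labels.csv")

    # 2. structure graphs
    graphs = load_graphs(records, corpus_dir, cutoff=cfg.graph.cutoff)

    # 3. dedup / split / balance
    prep_seed = stage_seed(cfg.seed, "prep")
    train_balanced, train_pairs, test = prepare_records(records, cfg, prep_seed)
    prep.write_labels_csv(train_balanced, out / "train.csv")
    prep.write_labels_csv(test, out / "test.csv")
    manifest["artifacts"]["train"] = str(out / "train.csv")
    manifest["artifacts"]["test"] = str(out / "test.csv")

    # 4. stage-1 pretraining, both encoders on one model object
    model = PepClipModel(
        cfg.encoders.to_model_config(seed=stage_seed(cfg.seed, "pretrain_text"))
    )
    text_state = pretrain(
        "text",
        train_balanced,
        _stage_cfg(cfg.pretrain_text, "pretrain_text", stage_seed(cfg.seed, "pretrain_text")),
        model=model,
    )
    checkpoint_save(text_state, out / "text_pretrained.npz")
    graph_state = pretrain(
        "graph",
        train_balanced,
        _stage_cfg(cfg.pretrain_graph, "pretrain_graph", stage_seed(cfg.seed, "pretrain_graph")),
        model=model,
        graphs=graphs,
    )
    checkpoint_save(graph_state, out / "graph_pretrained.npz")

    # stage-1 baseline accuracy of the text branch
    pre_preds = predict(model, {r.id: r.sequence for r in test}, cfg.eval.threshold)
    pre_report = evaluate(pre_preds, test, cfg.eval.threshold)

    # 5. contrastive alignment (graph encoder frozen)
    align_state = align(
        text_state,
        graph_state,
        train_pairs,
        graphs,
        _stage_cfg(cfg.align, "align", stage_seed(cfg.seed, "align")),
    )
    checkpoint_save(align_state, out / "aligned.npz")
    manifest["artifacts"]["checkpoints"] = [
        str(out / "text_pretrained.npz"),
        str(out / "graph_pretrained.npz"),
        str(out / "aligned.npz"),
    ]

    # 6. sequence-only inference on the held-out split
    preds = predict(model, {r.id: r.sequence for r in test}, cfg.eval.threshold)
    preds.to_csv(out / "predictions.csv", index=False)
    report = evaluate(preds, test, cfg.eval.threshold)
    result = {
        "stage1_text": pre_report.to_dict(),
        "aligned_text": report.to_dict(),
        "majority_baseline_percent": round(
            100.0 * max(
                sum(r.label == 1 for r in test), sum(r.label == 0 for r in test)
            ) / len(test),
            3,
        ),
    }
    (out / "report.json").write_text(json.dumps(result, indent=2))
    manifest["artifacts"]["predictions"] = str(out / "predictions.csv")
    manifest["artifacts"]["report"] = str(out / "report.json")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result
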
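"""Sequence-only inference and evaluation.

After alignment the graph model is discarded: prediction tokenizes the
sequence, runs the (updated) text encoder and applies the stage-1
classification head — no structural input is touched.  t-SNE exports
support qualitative inspection of the three embedding spaces (text
encoder, graph encoder, shared latent space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .model import PepClipModel
from .prep import LabeledSequence

__all__ = ["EvalReport", "TsneProjection", "predict", "evaluate", "tsne_export"]


@dataclass
class EvalReport:
    accuracy: float  # percent, three decimals
    n_test: int
    per_class_counts: dict
    threshold: float

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "n_test": self.n_test,
            "per_class_counts": self.per_class_counts,
            "threshold": self.threshold,
        }


@dataclass
class TsneProjection:
    coordinates: np.ndarray  # (N, d), d in {2, 3}
    labels: np.ndarray
    perplexity: float
    seed: int


def predict(
    model: PepClipModel,
    sequences: list[str] | dict[str, str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify peptides from sequence alone.

    Returns a frame with columns ``id``, ``probability``, ``label``
    (label = probability >= threshold).
    """
    if isinstance(sequences, dict):
        ids, seqs = list(sequences.keys()), list(sequences.values())
    else:
        ids, seqs = [f"seq{i}" for i in range(len(sequences))], list(sequences)
    if not seqs:
        raise ValueError("no sequences to predict")
    probs = np.concatenate(
        [model.text_probability(seqs[i : i + 64]) for i in range(0, len(seqs), 64)]
    )
    return pd.DataFrame(
        {"id": ids, "probability": probs, "label": (probs >= threshold).astype(int)}
    )


def evaluate(
    predictions: pd.DataFrame, truth: list[LabeledSequence], threshold: float = 0.5
) -> EvalReport:
    """Accuracy (percent, three decimals) of predictions against labels,
    matched by id."""
    truth_map = {r.id: r.label for r in truth}
    pred_ids = set(predictions["id"])
    if pred_ids != set(truth_map):
        raise ValueError(
            f"id mismatch between predictions and truth "
            f"({len(pred_ids ^ set(truth_map))} unmatched ids)"
        )
    merged = predictions.assign(truth=[truth_map[i] for i in predictions["id"]])
    correct = int((merged["label"] == merged["truth"]).sum())
    n = len(merged)
    counts = {
        "true_positive": int(((merged.label == 1) & (merged.truth == 1)).sum()),
        "true_negative": int(((merged.label == 0) & (merged.truth == 0)).sum()),
        "false_positive": int(((merged.label == 1) & (merged.truth == 0)).sum()),
        "false_negative": int(((merged.label == 0) & (merged.truth == 1)).sum()),
    }
    return EvalReport(
        accuracy=round(100.0 * correct / n, 3),
        n_test=n,
        per_class_counts=counts,
        threshold=threshold,
    )


def tsne_export(
    embeddings: np.ndarray,
    labels: np.ndarray,
    d: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
    ids: list[str] | None = None,
    out_csv=None,
) -> TsneProjection:
    """Seeded t-SNE projection of an embedding matrix into 2 or 3 dims."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if d not in (2, 3):
        raise ValueError("projection dimension must be 2 or 3")
    n = embeddings.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"n={n} is too small for perplexity {perplexity}; "
            f"use perplexity < {n / 3:.1f} (e.g. {max(2, n // 4)})"
        )
    tsne = TSNE(
        n_components=d,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact" if n < 500 else "barnes_hut",
    )
    coords = tsne.fit_transform(embeddings)
    if out_csv is not None:
        frame = {"id": ids if ids is not None else [f"seq{i}" for i in range(n)]}
        frame["label"] = labels
        for k in range(d):
            frame[f"c{k + 1}"] = coords[:, k]
        pd.DataFrame(frame).to_csv(out_csv, index=False)
    return TsneProjection(coordinates=coords, labels=labels, perplexity=perplexity, seed=seed)
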
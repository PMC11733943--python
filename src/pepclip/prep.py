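"""Labeled-corpus preparation: deduplication, oversampling, splitting.

Two deduplication conventions are supported because hemolysis-style and
nonfouling-style corpora need different ones: sequences recorded with
*conflicting* labels are unreliable and dropped entirely, while exact
(sequence, label) repeats are collapsed to one representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSequence",
    "SplitResult",
    "resolve_duplicates",
    "oversample_balance",
    "split_train_test",
    "class_fraction",
    "read_labels_csv",
    "write_labels_csv",
]


@dataclass(frozen=True)
class LabeledSequence:
    id: str
    sequence: str
    label: int
    structure_ref: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id}: label must be 0 or 1")


@dataclass
class SplitResult:
    train: list[LabeledSequence]
    test: list[LabeledSequence]
    seed: int
    fraction: float = field(default=0.8)


def resolve_duplicates(
    records: list[LabeledSequence], mode: str = "conflict_drop"
) -> list[LabeledSequence]:
    """Remove duplicate sequences.

    ``conflict_drop``: any sequence string that occurs with both labels is
    removed entirely (every copy).  ``same_label_collapse``: identical
    (sequence, label) pairs keep a single representative.  Both modes also
    collapse residual exact duplicates, and both preserve input order.
    """
    if mode not in ("conflict_drop", "same_label_collapse"):
        raise ValueError(f"unknown deduplication mode {mode!r}")
    labels_by_seq: dict[str, set[int]] = {}
    for r in records:
        labels_by_seq.setdefault(r.sequence, set()).add(r.label)
    out: list[LabeledSequence] = []
    seen: set[tuple[str, int]] = set()
    for r in records:
        if mode == "conflict_drop" and len(labels_by_seq[r.sequence]) > 1:
            continue
        key = (r.sequence, r.label)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def oversample_balance(
    records: list[LabeledSequence], seed: int = 0
) -> list[LabeledSequence]:
    """Duplicate minority-class records (with replacement, seeded) until
    both class counts are equal.  Originals are always retained."""
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos or not neg:
        raise ValueError("oversampling requires both classes to be present")
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    deficit = len(majority) - len(minority)
    rng = np.random.default_rng(seed)
    extra = [minority[i] for i in rng.integers(0, len(minority), size=deficit)]
    return list(records) + extra


def split_train_test(
    records: list[LabeledSequence],
    fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> SplitResult:
    """Seeded shuffle-and-partition into disjoint train/test sets.

    Stratified by label by default so small corpora keep a stable test
    composition; train size is round(fraction * n) within each stratum.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    strata = (
        [[r for r in records if r.label == 1], [r for r in records if r.label == 0]]
        if stratify
        else [list(records)]
    )
    train: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    for group in strata:
        if not group:
            continue
        order = rng.permutation(len(group))
        n_train = int(np.floor(fraction * len(group) + 0.5))
        n_train = min(max(n_train, 0), len(group))
        train += [group[i] for i in order[:n_train]]
        test += [group[i] for i in order[n_train:]]
    return SplitResult(train=train, test=test, seed=seed, fraction=fraction)


def class_fraction(records_or_counts) -> tuple[float, float]:
    """Percentage of positive and negative records, to three decimals.

    Accepts either a record list or a ``(n_positive, n_negative)`` pair.
    """
    if isinstance(records_or_counts, tuple):
        n_pos, n_neg = records_or_counts
    else:
        labels = [r.label for r in records_or_counts]
        n_pos, n_neg = sum(labels), len(labels) - sum(labels)
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("no records")
    return (
        round(100.0 * n_pos / total, 3),
        round(100.0 * n_neg / total, 3),
    )


def read_labels_csv(path) -> list[LabeledSequence]:
    df = pd.read_csv(path, dtype={"id": str, "sequence": str})
    cols = {"id", "sequence", "label"}
    if not cols.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(cols)}")
    has_ref = "structure_ref" in df.columns
    return [
        LabeledSequence(
            id=row.id,
            sequence=row.sequence,
            label=int(row.label),
            structure_ref=(str(row.structure_ref) if has_ref else None),
        )
        for row in df.itertuples()
    ]


def write_labels_csv(records: list[LabeledSequence], path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence for r in records],
            "label": [r.label for r in records],
            "structure_ref": [r.structure_ref or "" for r in records],
        }
    )
    df.to_csv(path, index=False)
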
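"""Validation reservation and class balancing.

A fixed number of names per class is reserved for validation (sampled
without replacement), then the remaining training names are resampled
with replacement until every class holds exactly the balance target.
Classes above the target are sampled down to it, so all classes end
exactly equal.  Validation is drawn before balancing, and because the
input is deduplicated, no name can appear on both sides of the split.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import LabeledOutlet, UNCLASSIFIED

__all__ = ["SplitSet", "make_split", "balance_train", "write_split_csv"]


@dataclass
class SplitSet:
    """Disjoint training/validation partition plus the balanced
    (resampled) training corpus."""

    train_unique: list[LabeledOutlet]
    validation: list[LabeledOutlet]
    train_balanced: list[LabeledOutlet] = field(default_factory=list)
    seed: int = 0
    n_val_per_class: int = 0
    balance_target: int = 0

    def class_counts(self, which: str = "train_unique") -> dict[str, int]:
        part = getattr(self, which)
        counts: dict[str, int] = defaultdict(int)
        for rec in part:
            counts[rec.cuisine] += 1
        return dict(counts)


def make_split(
    records: Sequence[LabeledOutlet], n_val_per_class: int, seed: int
) -> SplitSet:
    """Reserve ``n_val_per_class`` records per class for validation.

    Sampling is without replacement and reproducible under ``seed``.
    Unclassified records must be removed beforehand; a class with too few
    records to leave a non-empty training remainder is an error.
    """
    bad = [r for r in records if r.cuisine == UNCLASSIFIED]
    if bad:
        raise ValueError(
            f"{len(bad)} unclassified records present; remove them before splitting"
        )
    by_class: dict[str, list[LabeledOutlet]] = defaultdict(list)
    for rec in records:
        by_class[rec.cuisine].append(rec)
    for cls, members in sorted(by_class.items()):
        if len(members) <= n_val_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(members)} records; "
                f"> {n_val_per_class} are required to reserve a validation sample"
            )
    rng = np.random.default_rng(seed)
    validation: list[LabeledOutlet] = []
    train: list[LabeledOutlet] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        idx = rng.choice(len(members), size=n_val_per_class, replace=False)
        chosen = set(int(i) for i in idx)
        validation.extend(members[i] for i in sorted(chosen))
        train.extend(m for i, m in enumerate(members) if i not in chosen)
    return SplitSet(
        train_unique=train,
        validation=validation,
        seed=seed,
        n_val_per_class=n_val_per_class,
    )


def balance_train(split: SplitSet, balance_target: int, seed: int) -> SplitSet:
    """Fill ``train_balanced``: exactly ``balance_target`` records per
    class, drawn with replacement from that class's unique training
    records (classes above the target are likewise resampled down)."""
    if not split.train_unique:
        raise ValueError("train_unique is empty")
    by_class: dict[str, list[LabeledOutlet]] = defaultdict(list)
    for rec in split.train_unique:
        by_class[rec.cuisine].append(rec)
    rng = np.random.default_rng(seed)
    balanced: list[LabeledOutlet] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        idx = rng.integers(0, len(members), size=balance_target)
        balanced.extend(members[int(i)] for i in idx)
    split.train_balanced = balanced
    split.balance_target = balance_target
    return split


def write_split_csv(split: SplitSet, path) -> None:
    """Audit manifest: one row per record with its partition."""
    rows = [
        {"name": r.name, "cuisine": r.cuisine, "partition": part}
        for part, records in (
            ("train", split.train_unique),
            ("validation", split.validation),
            ("train_balanced", split.train_balanced),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=["name", "cuisine", "partition"]).to_csv(path, index=False)
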
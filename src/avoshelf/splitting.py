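"""Leakage-free grouped 70/15/15 splitting and random oversampling.

Every photograph of a fruit (both sides, all days) is assigned to exactly
one of train/validation/test, so no fruit leaks information across
subsets.  Because each fruit traverses many stages, exact per-stage
stratification is impossible; a greedy seeded heuristic keeps per-stage
photograph shares close to the target fractions.  The training set is then
balanced by random oversampling (duplicating randomly chosen minority-stage
records until all stages match the majority count); validation and test
retain their natural distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DatasetSplit", "grouped_stratified_split", "oversample_training"]

_SUBSETS = ("train", "val", "test")


@dataclass
class DatasetSplit:
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    train_records_oversampled: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        sets = [self.train_ids, self.val_ids, self.test_ids]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("subset id sets must be pairwise disjoint")

    def subset_of(self, sample_id) -> str:
        for name, ids in zip(_SUBSETS, (self.train_ids, self.val_ids, self.test_ids)):
            if sample_id in ids:
                return name
        raise KeyError(f"sample {sample_id} not in any subset")

    def assignments(self) -> pd.DataFrame:
        rows = [(sid, name) for name, ids in
                zip(_SUBSETS, (self.train_ids, self.val_ids, self.test_ids))
                for sid in sorted(ids)]
        return pd.DataFrame(rows, columns=["sample_id", "subset"]).sort_values("sample_id",
                                                                               ignore_index=True)


def grouped_stratified_split(db, fractions=(0.70, 0.15, 0.15), seed: int = 0,
                             index: int = 10) -> DatasetSplit:
    """Assign whole samples to train/val/test, balancing stage composition.

    Samples are visited in seeded random order, largest (most photographs)
    first; each goes to the subset where it least overshoots the subset's
    per-stage record targets (``fraction x`` overall stage counts), with a
    penalty for exceeding the subset's overall share.  Deterministic for a
    fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    df = db.records
    col = f"ri{index}"
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) < 3:
        raise ValueError("need at least as many samples as subsets")

    stage_counts = (df.groupby(["sample_id", col]).size().unstack(fill_value=0))
    stages = stage_counts.columns
    totals = stage_counts.sum(axis=0).to_numpy(dtype=float)
    grand = totals.sum()

    rng = np.random.default_rng(seed)
    order = rng.permutation(sample_ids)
    sizes = stage_counts.sum(axis=1)
    order = sorted(order, key=lambda sid: (-sizes[sid],
                                           rng.random()))

    assigned = {name: np.zeros(len(stages)) for name in _SUBSETS}
    assign_total = dict.fromkeys(_SUBSETS, 0.0)
    result: dict[str, set] = {name: set() for name in _SUBSETS}
    for sid in order:
        vec = stage_counts.loc[sid].to_numpy(dtype=float)
        best, best_cost = None, np.inf
        for name, frac in zip(_SUBSETS, fractions):
            target = frac * totals
            after = assigned[name] + vec
            cost = float(np.sum(np.maximum(after - target, 0.0) ** 2))
            cost += max(assign_total[name] + vec.sum() - frac * grand, 0.0) ** 2
            # mild preference for the subset furthest below its overall share
            cost -= 1e-9 * (frac * grand - assign_total[name])
            if cost < best_cost - 1e-12:
                best, best_cost = name, cost
        assigned[best] += vec
        assign_total[best] += vec.sum()
        result[best].add(sid)

    for name in _SUBSETS:   # no subset may end empty
        if not result[name]:
            donor = max(_SUBSETS, key=lambda n: len(result[n]))
            moved = sorted(result[donor])[0]
            result[donor].discard(moved)
            result[name].add(moved)
    return DatasetSplit(train_ids=frozenset(result["train"]),
                        val_ids=frozenset(result["val"]),
                        test_ids=frozenset(result["test"]),
                        fractions=fractions)


def oversample_training(split: DatasetSplit, db, seed: int = 0,
                        index: int = 10) -> pd.DataFrame:
    """Random oversampling of the training records to equal stage counts.

    Duplicates randomly chosen training records per stage until every stage
    matches the majority stage's count.  Only training records are touched;
    a stage absent from training stays at zero (reported via warning).
    Returns the oversampled record multiset (original rows first).
    """
    import warnings

    col = f"ri{index}"
    train = db.records[db.records["sample_id"].isin(split.train_ids)]
    if train.empty:
        raise ValueError("training subset is empty")
    counts = train[col].value_counts()
    target = int(counts.max())
    absent = [s for s in range(1, index + 1) if s not in counts.index]
    if absent:
        warnings.warn(f"stages {absent} absent from training; left at zero")
    rng = np.random.default_rng(seed)
    parts = [train]
    for stage, n in counts.items():
        need = target - int(n)
        if need > 0:
            pool = train[train[col] == stage]
            picks = rng.integers(0, len(pool), size=need)
            parts.append(pool.iloc[picks])
    out = pd.concat(parts, ignore_index=True)
    split.train_records_oversampled = out
    return out
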
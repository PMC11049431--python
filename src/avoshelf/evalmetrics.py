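"""Ordinal accuracy metrics, confusion matrices, and two-model error overlap.

Two accuracy views are supported for two-sided photography:

* picture mode — fraction of photographs whose predicted stage is within
  ``margin`` stages of the truth;
* sample mode — fraction of (sample, day) pairs where *at least one* of
  the two sides satisfies the margin criterion (a fruit is assessed
  correctly if either side is).

Sample-mode accuracy therefore dominates picture-mode accuracy, and both
are nondecreasing in the margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "OverlapSummary", "accuracy",
           "per_stage_accuracy", "confusion_matrix", "error_overlap"]

_PAIR = ["sample_id", "day"]


def _within(preds: pd.DataFrame, margin: int) -> pd.Series:
    return (preds["predicted_stage"] - preds["true_stage"]).abs() <= margin


def accuracy(preds: pd.DataFrame, mode: str = "picture", margin: int = 0) -> float:
    """Margin-of-error accuracy by picture or by sample (best side)."""
    if preds.empty:
        raise ValueError("no predictions")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    hit = _within(preds, margin)
    if mode == "picture":
        return float(hit.mean())
    if mode == "sample":
        sides = preds.groupby(_PAIR)["side"].nunique()
        if (sides < 2).any():
            warnings.warn(f"{int((sides < 2).sum())} sample-days with a single side; "
                          "counted on available sides")
        return float(hit.groupby([preds[c] for c in _PAIR]).any().mean())
    raise ValueError(f"unknown mode {mode!r}")


def per_stage_accuracy(preds: pd.DataFrame, mode: str = "picture",
                       margin: int = 0) -> dict[int, float]:
    """Accuracy restricted to each true stage; absent stages are omitted."""
    out: dict[int, float] = {}
    for stage, sub in preds.groupby("true_stage"):
        out[int(stage)] = accuracy(sub, mode=mode, margin=margin)
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray          # (K, K); rows = true stage, cols = predicted
    stages: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.stages, name="true")
        return pd.DataFrame(self.counts, index=idx,
                            columns=pd.Index(self.stages, name="predicted"))


def confusion_matrix(preds: pd.DataFrame, n_stages: int | None = None) -> ConfusionMatrix:
    """Stage-by-stage count matrix; trace/total equals margin-0 picture accuracy."""
    if preds.empty:
        raise ValueError("no predictions")
    k = n_stages or int(max(preds["true_stage"].max(), preds["predicted_stage"].max()))
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(preds["true_stage"], preds["predicted_stage"]):
        counts[t - 1, p - 1] += 1
    return ConfusionMatrix(counts=counts, stages=tuple(range(1, k + 1)))


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of a shared test set by the margin-0 correctness of two models."""

    errors_only_a: int
    errors_only_b: int
    errors_shared: int
    correct_both: int

    @property
    def total(self) -> int:
        return self.errors_only_a + self.errors_only_b + self.errors_shared + self.correct_both

    @property
    def overlap_fraction_of_errors(self) -> float:
        """Shared errors as a fraction of all records either model got wrong."""
        any_err = self.errors_only_a + self.errors_only_b + self.errors_shared
        return self.errors_shared / any_err if any_err else 0.0


def error_overlap(preds_a: pd.DataFrame, preds_b: pd.DataFrame) -> OverlapSummary:
    """Classify each shared record by which model(s) erred at margin 0."""
    key = ["sample_id", "side", "day"]
    a = preds_a.set_index(key).sort_index()
    b = preds_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("prediction sets cover different records")
    if not (a["true_stage"] == b["true_stage"]).all():
        raise ValueError("prediction sets disagree on true stages")
    err_a = (a["predicted_stage"] != a["true_stage"]).to_numpy()
    err_b = (b["predicted_stage"] != b["true_stage"]).to_numpy()
    return OverlapSummary(
        errors_only_a=int((err_a & ~err_b).sum()),
        errors_only_b=int((~err_a & err_b).sum()),
        errors_shared=int((err_a & err_b).sum()),
        correct_both=int((~err_a & ~err_b).sum()),
    )
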
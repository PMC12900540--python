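"""Evaluation of predicted versus held-out region labels.

Two headline metrics: the adjusted Rand index (chance-corrected partition
agreement, in [-1, 1]) and clustering accuracy.  Because the classifier
transfers the source slice's region *names* to the target, the default
accuracy is semantic — exact name equality per spot.  A matched mode
(best accuracy over class-name bijections, via optimal assignment on the
confusion matrix) is provided for comparison with label-free clustering
tools whose cluster ids carry no meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score


@dataclass
class EvalReport:
    ari: float
    ca: float
    confusion: pd.DataFrame  # true classes x predicted classes, counts
    confusion_normalized: pd.DataFrame  # rows sum to 1 for non-empty classes
    precision: dict[str, float]
    recall: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "ari": self.ari,
            "ca": self.ca,
            "confusion": self.confusion.to_dict(),
            "confusion_normalized": self.confusion_normalized.to_dict(),
            "precision": self.precision,
            "recall": self.recall,
        }

    def write(self, json_path, confusion_csv=None) -> None:
        Path(json_path).write_text(json.dumps(self.to_dict(), indent=2, default=float))
        if confusion_csv is not None:
            self.confusion.to_csv(confusion_csv)


def _check_lengths(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError(f"label lengths differ: {len(y_true)} vs {len(y_pred)}")
    return y_true, y_pred


def adjusted_rand_index(y_true, y_pred) -> float:
    """Permutation-model ARI from the contingency table."""
    y_true, y_pred = _check_lengths(y_true, y_pred)
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    return float(adjusted_rand_score(y_true.astype(str), y_pred.astype(str)))


def contingency(y_true, y_pred) -> pd.DataFrame:
    y_true, y_pred = _check_lengths(y_true, y_pred)
    return pd.crosstab(
        pd.Series(y_true.astype(str), name="true"),
        pd.Series(y_pred.astype(str), name="pred"),
    )


def clustering_accuracy(y_true, y_pred, mode: str = "semantic") -> float:
    """Fraction of spots labeled correctly.

    `semantic`: predicted name must equal the true name (annotation
    transfer).  `matched`: best accuracy over bijective class renamings,
    solved exactly by linear assignment on the contingency table.
    """
    y_true, y_pred = _check_lengths(y_true, y_pred)
    if mode == "semantic":
        if not set(y_true.astype(str)) & set(y_pred.astype(str)):
            raise ValueError(
                "true and predicted label names are disjoint; use mode='matched'"
            )
        return float(np.mean(y_true.astype(str) == y_pred.astype(str)))
    if mode == "matched":
        table = contingency(y_true, y_pred).to_numpy()
        # pad to square so the assignment is a bijection on the larger side
        k = max(table.shape)
        padded = np.zeros((k, k))
        padded[: table.shape[0], : table.shape[1]] = table
        r, c = linear_sum_assignment(-padded)
        return float(padded[r, c].sum() / len(y_true))
    raise ValueError(f"unknown mode {mode!r}")


def confusion_report(y_true, y_pred) -> EvalReport:
    """Full report: ARI, semantic CA, confusion counts, precision/recall."""
    table = contingency(y_true, y_pred)
    # square it on the union of names so the diagonal is well defined
    names = sorted(set(table.index) | set(table.columns))
    table = table.reindex(index=names, columns=names, fill_value=0)
    counts = table.to_numpy(dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    diag = np.diag(counts)
    precision = {
        n: float(diag[i] / col_sums[i]) if col_sums[i] > 0 else float("nan")
        for i, n in enumerate(names)
    }
    recall = {
        n: float(diag[i] / row_sums[i, 0]) if row_sums[i, 0] > 0 else float("nan")
        for i, n in enumerate(names)
    }
    return EvalReport(
        ari=adjusted_rand_index(y_true, y_pred),
        ca=clustering_accuracy(y_true, y_pred, mode="semantic"),
        confusion=table,
        confusion_normalized=pd.DataFrame(normalized, index=names, columns=names),
        precision=precision,
        recall=recall,
    )
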
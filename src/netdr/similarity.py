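"""Module-similarity statistic: ranked gene lists → ROC/AUC → combined score.

A metric's gene ranking on one module is scored against the member set of
the other module as a retrieval problem: at each of 100 percentile cutoffs
(top 1%, 2%, …, 100% of the ranked list) a confusion matrix gives one
(FPR, TPR) point; the trapezoidal area under the resulting curve is the
module-similarity AUC.  A drug's repositioning score is the geometric mean
of the two directions (AUC_DAPN: drug module ranked, disease members as
reference; AUC_DGN: roles swapped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from netdr.metrics import ScoreTable


class UndefinedAUCError(ValueError):
    """The reference set is empty on, or covers, the ranked list; TPR or FPR
    has a zero denominator and the AUC is undefined."""


@dataclass(frozen=True)
class RocCurve:
    """ROC points (FPR, TPR) sorted by FPR, with trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float


@dataclass
class DrugResult:
    """Per-drug, per-metric similarity result row."""

    drug_id: str
    metric: str
    auc_dapn: float
    auc_dgn: float
    combined_auc: float
    f1: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    n_ranked: int = 0
    n_reference: int = 0

    @property
    def is_na(self) -> bool:
        return math.isnan(self.combined_auc)


def rank_genes(table: ScoreTable) -> list[str]:
    """Genes sorted by score in the table's direction; ties break by gene ID.

    Descending metrics put the highest score first; neighborhood scoring
    ranks ascending.  The lexicographic tie-break makes the ranking, and
    everything downstream, deterministic.
    """
    if not table.scores:
        raise ValueError("cannot rank an empty score table")
    if table.rank_direction == "ascending":
        return sorted(table.scores, key=lambda g: (table.scores[g], g))
    return sorted(table.scores, key=lambda g: (-table.scores[g], g))


def _cutoffs(n: int, n_thresholds: int) -> np.ndarray:
    """Rank cutoffs at 1%, 2%, …, 100% of the list (round-half-up, floor 1,
    deduplicated)."""
    p = np.arange(1, n_thresholds + 1, dtype=float)
    k = np.floor(p * n / n_thresholds + 0.5).astype(int)
    k = np.clip(k, 1, n)
    return np.unique(k)


def roc_auc(
    ranked: Sequence[str],
    reference: Iterable[str],
    n_thresholds: int = 100,
    anchors: bool = True,
) -> RocCurve:
    """ROC curve and AUC of a ranked gene list against a reference gene set.

    At each cutoff k, TP is the number of reference genes in the top k,
    FP = k − TP, FN and TN follow; TPR = TP/(TP+FN), FPR = FP/(FP+TN).
    ``anchors`` adds (0,0) and (1,1), which the 1%…100% grid does not
    contain.  The reference is first restricted to the ranked genes.

    Raises
    ------
    UndefinedAUCError
        If the restricted reference is empty or covers every ranked gene.
    """
    ranked = list(ranked)
    ref = set(reference) & set(ranked)
    n = len(ranked)
    n_pos = len(ref)
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"reference covers {n_pos}/{n} ranked genes; TPR/FPR undefined"
        )
    flags = np.fromiter((g in ref for g in ranked), dtype=bool, count=n)
    cum_tp = np.cumsum(flags)
    ks = _cutoffs(n, n_thresholds)
    tp = cum_tp[ks - 1]
    fp = ks - tp
    tpr = tp / n_pos
    fpr = fp / n_neg
    pts = np.column_stack([fpr, tpr])
    if anchors:
        pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    pts = np.unique(pts, axis=0)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(points=tuple(map(tuple, pts)), auc=auc)


def confusion_metrics(
    ranked: Sequence[str],
    reference: Iterable[str],
    k: int | None = None,
) -> tuple[float, float, float]:
    """Precision, recall and F1 of the top-k prediction set.

    Default k is the size of the reference restricted to the ranked list
    (the break-even cutoff where precision and recall share a denominator
    scale).  F1 is 0 when precision and recall are both 0.
    """
    ranked = list(ranked)
    ref = set(reference) & set(ranked)
    if not ref:
        raise UndefinedAUCError("reference has no overlap with the ranked genes")
    if k is None:
        k = len(ref)
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}], got {k}")
    tp = sum(1 for g in ranked[:k] if g in ref)
    precision = tp / k
    recall = tp / len(ref)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def combined_auc(auc_dapn: float, auc_dgn: float) -> float:
    """Geometric mean of the two directional AUCs — the drug's score."""
    if not (0.0 <= auc_dapn <= 1.0 and 0.0 <= auc_dgn <= 1.0):
        raise ValueError(f"AUCs must be in [0, 1], got ({auc_dapn}, {auc_dgn})")
    return math.sqrt(auc_dapn * auc_dgn)


def write_roc_points(curve: RocCurve, path) -> None:
    """Export ROC points as a TSV for plotting."""
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in curve.points:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
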
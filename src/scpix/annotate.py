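"""Cell-type calls, open-set (unknown type) detection and scoring.

A query cell whose maximum class probability falls below a calibrated
threshold is flagged ``unknown``: none of the reference types explains it
well, the signature of a cell type absent from the reference. The threshold
is the 1% quantile of maximum probabilities over held-out *reference*
validation cells, so roughly 1% of in-distribution cells are sacrificed in
exchange for sensitivity to genuinely novel populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, confusion_matrix, f1_score


def calibrate_unknown_threshold(
    reference_val_proba: np.ndarray, quantile: float = 0.01
) -> float:
    """Empirical ``quantile`` of max-probability over reference validation cells.

    Lower-interpolation convention, so at most a ``quantile`` fraction of the
    calibration cells fall strictly below the returned threshold.
    """
    proba = np.asarray(reference_val_proba, dtype=float)
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0,1)")
    if proba.ndim != 2 or len(proba) < 10:
        raise ValueError("need a (cells >= 10, classes) probability matrix")
    max_p = proba.max(axis=1)
    if np.allclose(max_p, max_p[0]):
        warnings.warn(
            "all calibration max-probabilities identical; threshold degenerate",
            stacklevel=2,
        )
        return float(max_p[0])
    return float(np.quantile(max_p, quantile, method="lower"))


@dataclass
class PredictionResult:
    """Per-cell calls: argmax label, max probability, unknown flag.

    ``audit_label`` keeps the argmax class even for unknown-flagged cells;
    ``label`` replaces it with ``unknown_label`` for those cells.
    """

    cell_ids: np.ndarray
    class_names: List[str]
    proba: np.ndarray
    audit_label: np.ndarray
    max_p: np.ndarray
    unknown: np.ndarray
    threshold: float
    unknown_label: str = "Unknown"

    @property
    def label(self) -> np.ndarray:
        return np.where(self.unknown, self.unknown_label, self.audit_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.cell_ids.astype(str),
                "predicted_label": self.label.astype(str),
                "max_probability": self.max_p,
                "unknown_flag": self.unknown,
                "audit_label": self.audit_label.astype(str),
            }
        )


def annotate(
    proba: np.ndarray,
    class_names: List[str],
    threshold: float,
    cell_ids: Optional[np.ndarray] = None,
    unknown_label: str = "Unknown",
) -> PredictionResult:
    """Argmax calls with unknown flags (``max_p < threshold``).

    Exact probability ties go to the lexicographically smallest class name.
    """
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[1] != len(class_names):
        raise ValueError("probability matrix shape does not match class names")
    sums = proba.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1 (within 1e-4)")
    # argmax over columns ordered by class name implements the tie rule
    name_order = np.argsort(np.asarray(class_names, dtype=object).astype(str))
    arg_in_sorted = proba[:, name_order].argmax(axis=1)
    audit = np.asarray(class_names, dtype=object)[name_order[arg_in_sorted]]
    max_p = proba.max(axis=1)
    unknown = max_p < threshold
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(len(proba))], dtype=object)
    return PredictionResult(
        cell_ids=np.asarray(cell_ids, dtype=object),
        class_names=list(class_names),
        proba=proba,
        audit_label=audit,
        max_p=max_p,
        unknown=unknown,
        threshold=float(threshold),
        unknown_label=unknown_label,
    )


def evaluate_annotation(
    pred: PredictionResult,
    truth: np.ndarray,
    novel_label: Optional[str] = None,
    unknown_counts_correct_for_novel: bool = True,
) -> Dict:
    """Score predictions against ground-truth types.

    Accuracy is the exact-match fraction; unknown-flagged cells count as
    incorrect unless the truth is the designated ``novel_label`` (then the
    unknown call is the correct one). Also returns the adjusted Rand index of
    the two labelings, macro-averaged F1, the confusion matrix, and — when a
    novel label is given — the novel-type detection rate (fraction of truth-
    novel cells flagged unknown) and the false-unknown rate on known cells.
    """
    truth = np.asarray(truth, dtype=object).astype(str)
    if len(truth) != len(pred.max_p):
        raise ValueError("truth labels not aligned to predictions")
    called = pred.label.astype(str)
    if novel_label is not None and unknown_counts_correct_for_novel:
        correct = np.where(
            truth == str(novel_label), pred.unknown, (called == truth) & ~pred.unknown
        )
    else:
        correct = (called == truth) & ~pred.unknown
    labels_union = sorted(set(truth) | set(called))
    cm = confusion_matrix(truth, called, labels=labels_union)
    metrics = {
        "accuracy": float(correct.mean()),
        "ari": float(adjusted_rand_score(truth, called)),
        "macro_f1": float(f1_score(truth, called, average="macro", zero_division=0)),
        "confusion_labels": labels_union,
        "confusion": cm,
        "n_unknown": int(pred.unknown.sum()),
    }
    if novel_label is not None:
        is_novel = truth == str(novel_label)
        metrics["novel_detection_rate"] = (
            float(pred.unknown[is_novel].mean()) if is_novel.any() else np.nan
        )
        metrics["known_unknown_rate"] = (
            float(pred.unknown[~is_novel].mean()) if (~is_novel).any() else np.nan
        )
        known = ~is_novel
        if known.any():
            metrics["known_accuracy"] = float(
                ((called == truth) & ~pred.unknown)[known].mean()
            )
    return metrics


def macro_auroc_auprc(
    proba: np.ndarray, class_names: List[str], truth: np.ndarray
) -> Dict[str, float]:
    """One-vs-rest macro AUROC/AUPRC over classes present in the truth."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    truth = np.asarray(truth, dtype=object).astype(str)
    aurocs, auprcs = [], []
    for j, cls in enumerate(class_names):
        y = (truth == str(cls)).astype(int)
        if y.min() == y.max():
            continue
        aurocs.append(roc_auc_score(y, proba[:, j]))
        auprcs.append(average_precision_score(y, proba[:, j]))
    return {
        "macro_auroc": float(np.mean(aurocs)) if aurocs else np.nan,
        "macro_auprc": float(np.mean(auprcs)) if auprcs else np.nan,
    }
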
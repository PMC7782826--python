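"""Challenge-style "gross" evaluation metrics.

The gross (overall) AUPRC and AUROC pool the scored samples of *all* records
before thresholding, so longer records weigh proportionally more — unlike a
plain mean of per-record scores.  Precision/recall (and TPR/FPR) are
evaluated on the fixed cutoff grid t_j = j/1000, j = 0..1000, with samples
counted as predicted-positive when their probability is >= t_j, and the
areas are

    AUPRC = sum_j P_j (R_j - R_{j+1}),          R_1001 := 0,
    AUROC = sum_j (TPR_j + TPR_{j+1})/2 * (FPR_j - FPR_{j+1}),

with (TPR, FPR)_1001 := (0, 0) and P_j := 1 when nothing is above the
cutoff (extending the PR curve to recall 0).  The AUPRC of a constant
predictor equals the pooled arousal prevalence exactly, which is why the
prevalence is reported as the AUPRC baseline.  Samples labeled -1
(non-scored) are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    PairingError,
    ParameterError,
    UndefinedMetricError,
)

N_CUTOFFS = 1000  # grid t_j = j / N_CUTOFFS, j = 0..N_CUTOFFS


def _coerce_labels(labels) -> np.ndarray:
    values = getattr(labels, "values", labels)
    return np.asarray(values)


def _coerce_predictions(predictions) -> np.ndarray:
    values = getattr(predictions, "probabilities", predictions)
    return np.asarray(values, dtype=np.float64)


def _pool(labels: Sequence, predictions: Sequence):
    ys, ps = [], []
    if len(labels) != len(predictions):
        raise PairingError("label and prediction lists differ in length")
    for lab, pred in zip(labels, predictions):
        y = _coerce_labels(lab)
        p = _coerce_predictions(pred)
        if y.shape != p.shape:
            raise AlignmentError(
                f"label length {y.shape} != prediction length {p.shape}"
            )
        scored = y >= 0
        ys.append(y[scored])
        ps.append(p[scored])
    y = np.concatenate(ys) if ys else np.empty(0, dtype=np.int8)
    p = np.concatenate(ps) if ps else np.empty(0)
    return y, p


def _counts_above_grid(y: np.ndarray, p: np.ndarray):
    """Per grid cutoff: (# positives >= t_j, # samples >= t_j)."""
    cuts = np.arange(N_CUTOFFS + 1) / N_CUTOFFS
    p_sorted = np.sort(p)
    pos_sorted = np.sort(p[y == 1])
    n_above = p.size - np.searchsorted(p_sorted, cuts, side="left")
    pos_above = pos_sorted.size - np.searchsorted(pos_sorted, cuts, side="left")
    return pos_above.astype(np.float64), n_above.astype(np.float64)


def gross_auprc(labels: Sequence, predictions: Sequence) -> float:
    """Record-length-weighted area under the precision-recall curve on the
    pooled scored samples.  Undefined (raises) without any arousal sample."""
    y, p = _pool(labels, predictions)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined: no arousal samples")
    pos_above, n_above = _counts_above_grid(y, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(n_above > 0, pos_above / n_above, 1.0)
    recall = pos_above / n_pos
    recall_next = np.append(recall[1:], 0.0)
    return float(np.sum(precision * (recall - recall_next)))


def gross_auroc(labels: Sequence, predictions: Sequence) -> float:
    """Gross AUROC on the same pooled samples and cutoff grid, integrated
    with the trapezoid rule.  Requires both classes among scored samples."""
    y, p = _pool(labels, predictions)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: single-class labels")
    pos_above, n_above = _counts_above_grid(y, p)
    tpr = pos_above / n_pos
    fpr = (n_above - pos_above) / n_neg
    tpr = np.append(tpr, 0.0)
    fpr = np.append(fpr, 0.0)
    return float(np.sum((tpr[:-1] + tpr[1:]) / 2.0 * (fpr[:-1] - fpr[1:])))


def segmentation_overlap(
    labels, predictions, threshold: float = 0.5
) -> tuple[float, float]:
    """Sorensen dice coefficient and Jaccard index of the binarized
    prediction against the arousal mask, over scored samples.

    Uses the standard evaluation conventions dice = 2|A&B| / (|A| + |B|)
    and jaccard = |A&B| / |A|B|; both are defined as 0 (with a warning)
    when both sets are empty.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    y = _coerce_labels(labels)
    p = _coerce_predictions(predictions)
    if y.shape != p.shape:
        raise AlignmentError("labels and predictions differ in length")
    scored = y >= 0
    a = y[scored] == 1
    b = p[scored] >= threshold
    inter = int(np.sum(a & b))
    size_sum = int(a.sum() + b.sum())
    union = int(np.sum(a | b))
    if size_sum == 0:
        warnings.warn("both masks empty: overlap defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 0.0
    dice = 2.0 * inter / size_sum
    jaccard = inter / union if union else 0.0
    return float(dice), float(jaccard)


@dataclass
class EvalReport:
    """Gross metrics plus a per-record table.

    ``prevalence`` is the arousal fraction of the pooled scored samples —
    the expected AUPRC of an uninformative predictor, reported as the
    baseline.  Records without any arousal sample get NaN per-record AUPRC
    (absent, not zero); single-class records get NaN AUROC.
    """

    gross_auprc: float
    gross_auroc: float
    prevalence: float
    per_record: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "gross_auprc": self.gross_auprc,
            "gross_auroc": self.gross_auroc,
            "prevalence": self.prevalence,
            "n_records": 0 if self.per_record is None else len(self.per_record),
        }

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        self.per_record.to_csv(path, index=False)


def evaluate_dataset(
    labels: Sequence,
    predictions: Sequence,
    record_ids: Optional[Sequence[str]] = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Gross metrics over the pooled samples plus independent per-record
    metrics.

    When both label and prediction objects carry ``record_id`` attributes
    the pairing is verified and a mismatch raises :class:`PairingError`.
    """
    if len(labels) == 0:
        raise ParameterError("need at least one record")
    ids = []
    for i, (lab, pred) in enumerate(zip(labels, predictions)):
        lid = getattr(lab, "record_id", None)
        pid = getattr(pred, "record_id", None)
        if lid is not None and pid is not None and lid != pid:
            raise PairingError(f"record id mismatch at index {i}: {lid} vs {pid}")
        if record_ids is not None:
            ids.append(record_ids[i])
        else:
            ids.append(pid or lid or f"record_{i}")

    rows = []
    for rid, lab, pred in zip(ids, labels, predictions):
        y = _coerce_labels(lab)
        p = _coerce_predictions(pred)
        scored = y >= 0
        n_scored = int(scored.sum())
        n_arousal = int((y == 1).sum())
        try:
            auprc = gross_auprc([y], [p])
        except UndefinedMetricError:
            auprc = np.nan
        try:
            auroc = gross_auroc([y], [p])
        except UndefinedMetricError:
            auroc = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dice, jaccard = segmentation_overlap(y, p, threshold)
        rows.append({
            "record_id": rid, "auprc": auprc, "auroc": auroc,
            "dice": dice, "jaccard": jaccard,
            "n_scored": n_scored, "n_arousal": n_arousal,
        })
    table = pd.DataFrame(rows)
    total_scored = int(table["n_scored"].sum())
    total_arousal = int(table["n_arousal"].sum())
    prevalence = total_arousal / total_scored if total_scored else float("nan")
    return EvalReport(
        gross_auprc=gross_auprc(labels, predictions),
        gross_auroc=gross_auroc(labels, predictions),
        prevalence=float(prevalence),
        per_record=table,
    )
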
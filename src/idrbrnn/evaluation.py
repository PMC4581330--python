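"""Assessment machinery for per-residue disorder predictions.

Binary measures at a decision threshold (a residue is called disordered when
its predicted probability is *equal to or greater than* the threshold):

    SE  = TP / (TP + FN)            sensitivity (recall)
    SP  = TN / (TN + FP)            specificity
    Prec = TP / (TP + FP)           precision
    Acc = (SE + SP) / 2             balanced accuracy
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FP)(TP+FN)(TN+FN))

plus threshold-free ROC and PR curves with trapezoidal areas, an
FPR-anchored threshold selector, termini trimming for internal-disorder
assessment, and AUC binned by identity to the best template.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BinaryMetrics:
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float
    mcc: float


@dataclass
class Curve:
    """A threshold sweep: ROC points are (FPR, TPR), PR points are
    (recall, precision)."""

    points: np.ndarray  # k x 2
    kind: str  # "ROC" or "PR"
    area: float


@dataclass
class ChainScores:
    """Per-chain disorder probabilities paired with true labels."""

    id: str
    scores: np.ndarray
    labels: np.ndarray


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    if isinstance(labels, str):
        y = np.frombuffer(labels.encode(), dtype=np.int8) - ord("0")
    else:
        y = np.asarray(labels)
    y = y.astype(np.intp)
    if s.shape != y.shape:
        raise ValueError(f"scores {s.shape} and labels {y.shape} differ in shape")
    return s, y


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the >=-threshold decision rule."""
    s, y = _as_arrays(scores, labels)
    if s.size == 0:
        raise ValueError("cannot compute a confusion matrix on empty input")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Threshold metrics; zero denominators give 0 (MCC convention) or 0.0
    for the rate in question."""
    se = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    acc = 0.5 * (se + sp)
    denom = (
        (c.tp + c.fp) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return BinaryMetrics(se, sp, prec, acc, mcc)


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP at each distinct score, descending (ties grouped)."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    return s[distinct], tps[distinct], fps[distinct]


def roc_curve(scores, labels) -> Curve:
    """ROC curve over the threshold sweep; trapezoidal AUC, which equals the
    Mann-Whitney pair-counting statistic with ties counted 1/2."""
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    _, tps, fps = _sweep(s, y)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return Curve(points=np.column_stack([fpr, tpr]), kind="ROC", area=area)


def auc_roc(scores, labels) -> float:
    return roc_curve(scores, labels).area


def pr_curve(scores, labels) -> Curve:
    """Precision-recall curve; area by trapezoid over recall (an
    approximation — no interpolation convention is canonical)."""
    s, y = _as_arrays(scores, labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    _, tps, fps = _sweep(s, y)
    recall = tps / n_pos
    precision = tps / (tps + fps)
    # anchor at recall 0 with the first point's precision
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    area = float(np.trapezoid(precision, recall))
    return Curve(points=np.column_stack([recall, precision]), kind="PR", area=area)


def auc_pr(scores, labels) -> float:
    return pr_curve(scores, labels).area


def threshold_at_fpr(scores, labels, target_fpr: float = 0.05) -> float:
    """Smallest threshold whose FPR on the given (training) data is at most
    ``target_fpr``.  Applying it elsewhere may realise a nearby FPR."""
    s, y = _as_arrays(scores, labels)
    neg = s[y == 0]
    if neg.size == 0 or (y == 1).sum() == 0:
        raise ValueError("threshold selection requires both classes present")
    candidates = np.unique(s)
    sentinel = candidates[-1] + 1e-6
    for t in candidates:
        if (neg >= t).mean() <= target_fpr:
            return float(t)
    warnings.warn(
        "target FPR unattainable at any observed score; returning a "
        "threshold above the maximum score",
        stacklevel=2,
    )
    return float(sentinel)


def trim_termini(chains: list[ChainScores], n_trim: int) -> list[ChainScores]:
    """Exclude n_trim residues at each chain end from scoring; chains with
    N <= 2*n_trim drop out entirely."""
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return list(chains)
    out = []
    for c in chains:
        if len(c.scores) > 2 * n_trim:
            out.append(
                ChainScores(
                    c.id,
                    c.scores[n_trim:-n_trim],
                    c.labels[n_trim:-n_trim],
                )
            )
    return out


def pool_chains(chains: list[ChainScores]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.concatenate([c.scores for c in chains])
    labels = np.concatenate([c.labels for c in chains])
    return scores, labels


def auc_by_identity_bins(
    chains: list[ChainScores],
    best_template_identity: dict[str, float],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Pool chains by best-template identity into half-open bins
    [0, 0.1), ..., [0.9, 1.0] (top bin closed) and compute the ROC AUC per
    bin; bins whose residues carry a single class get NaN."""
    n_bins = int(round(1.0 / bin_width))
    rows = []
    binned: list[list[ChainScores]] = [[] for _ in range(n_bins)]
    for c in chains:
        ident = best_template_identity[c.id]
        if not 0.0 <= ident <= 1.0:
            raise ValueError(f"identity {ident} outside [0, 1]")
        b = min(int(ident / bin_width), n_bins - 1)
        binned[b].append(c)
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        if not binned[b]:
            rows.append(dict(bin_lo=lo, bin_hi=hi, n_chains=0,
                             n_residues=0, auc=np.nan))
            continue
        s, y = pool_chains(binned[b])
        try:
            a = auc_roc(s, y)
        except ValueError:
            a = np.nan
        rows.append(
            dict(bin_lo=lo, bin_hi=hi, n_chains=len(binned[b]),
                 n_residues=int(s.size), auc=a)
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    counts: ConfusionCounts
    metrics: BinaryMetrics
    auc_roc: float
    auc_pr: float
    threshold: float

    def to_dict(self) -> dict:
        return dict(
            threshold=self.threshold,
            tp=self.counts.tp, fp=self.counts.fp,
            tn=self.counts.tn, fn=self.counts.fn,
            sensitivity=self.metrics.sensitivity,
            specificity=self.metrics.specificity,
            precision=self.metrics.precision,
            balanced_accuracy=self.metrics.balanced_accuracy,
            mcc=self.metrics.mcc,
            auc_roc=self.auc_roc,
            auc_pr=self.auc_pr,
        )


def write_curve_csv(curve: Curve, path) -> None:
    """Curve points as CSV (x, y columns named by kind)."""
    cols = ("fpr", "tpr") if curve.kind == "ROC" else ("recall", "precision")
    pd.DataFrame(curve.points, columns=cols).to_csv(path, index=False)


def evaluate_scores(scores, labels, threshold: float) -> EvalReport:
    """Full metric battery at a threshold, plus the threshold-free areas."""
    c = confusion(scores, labels, threshold)
    return EvalReport(
        counts=c,
        metrics=binary_metrics(c),
        auc_roc=auc_roc(scores, labels),
        auc_pr=auc_pr(scores, labels),
        threshold=threshold,
    )
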
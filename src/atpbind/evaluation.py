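"""Residue-level evaluation: confusion metrics, thresholding, ROC, and
biological concordance analyses.

Threshold-dependent metrics (accuracy, sensitivity, specificity, MCC) are
computed from integer confusion counts; the operating threshold is chosen
by maximising MCC over all distinct operating points, the standard protocol
for heavily imbalanced binding-site benchmarks. The boundary convention is
"score >= threshold => positive" everywhere. AUC is computed two ways — the
Mann-Whitney rank statistic and the trapezoidal area under the threshold-swept
ROC curve — and the two must agree to 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ContractError, DataError
from .io import AMINO_ACIDS, ProteinRecord

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "metrics_from_confusion",
    "confusion_from_scores",
    "optimal_threshold_by_mcc",
    "roc_auc",
    "confusion_from_residue_sets",
    "per_aa_recognition_rates",
    "composition_comparison",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    sen: float
    spe: float
    mcc: float
    auc: float | None = None
    threshold: float | None = None
    confusion: ConfusionMatrix | None = None
    degenerate_mcc: bool = False

    def summary(self) -> str:
        parts = [f"ACC {self.acc:.3f}", f"Sen {self.sen:.3f}", f"Spe {self.spe:.3f}",
                 f"MCC {self.mcc:.3f}"]
        if self.auc is not None:
            parts.append(f"AUC {self.auc:.3f}")
        if self.threshold is not None:
            parts.append(f"threshold {self.threshold:.4f}")
        return "  ".join(parts)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    area: float


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity and MCC from integer counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    factor of the denominator is zero the coefficient is reported as 0 and
    flagged degenerate.
    """
    if cm.total == 0:
        raise ContractError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = (tp + tn) / cm.total
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(acc=acc, sen=sen, spe=spe, mcc=mcc, confusion=cm,
                         degenerate_mcc=degenerate)


def _check_aligned(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ContractError(f"{scores.size} scores vs {labels.size} labels")
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("labels must be binary 0/1")
    return scores, labels


def confusion_from_scores(scores, labels, threshold: float) -> ConfusionMatrix:
    """Confusion counts calling positive iff score >= threshold (inclusive)."""
    scores, labels = _check_aligned(scores, labels)
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(calls & pos)),
        tn=int(np.sum(~calls & ~pos)),
        fp=int(np.sum(calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def _mcc_over_cuts(scores: np.ndarray, labels: np.ndarray):
    """MCC at every distinct operating point, scanned by descending score.

    Returns candidate thresholds (midpoints between consecutive distinct
    scores, plus endpoints giving the all-positive and all-negative calls)
    and the MCC achieved at each.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    # cumulative positives called at each cut: cut k calls the top-k scores
    distinct = np.nonzero(np.diff(s))[0]  # cut after these indices
    cum_tp = np.cumsum(y)
    ks = np.concatenate(([0], distinct + 1, [y.size])).astype(np.float64)
    tp = np.concatenate(([0], cum_tp[distinct], [n_pos])).astype(np.float64)
    fp = ks - tp
    fn = n_pos - tp
    tn = n_neg - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.maximum(denom, 1)), 0.0)
    # thresholds realising each cut: above max, midpoints, at-or-below min
    uniq_desc = s[np.concatenate((distinct, [y.size - 1]))]
    mids = (uniq_desc[:-1] + uniq_desc[1:]) / 2.0
    top = uniq_desc[0] + 1.0 if uniq_desc[0] >= 1.0 else (uniq_desc[0] + 1.0) / 2.0
    thresholds = np.concatenate(([top], mids, [uniq_desc[-1]]))
    return thresholds, mcc


def optimal_threshold_by_mcc(scores, labels) -> tuple[float, MetricsReport]:
    """Threshold maximising MCC, exact over all distinct operating points.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus the extreme all-positive / all-negative points; ties are broken
    towards the smallest threshold.
    """
    scores, labels = _check_aligned(scores, labels)
    if labels.min() == labels.max():
        raise DataError("both classes required to choose a threshold")
    thresholds, mccs = _mcc_over_cuts(scores, labels)
    best_mcc = mccs.max()
    # ties -> smallest threshold
    best_t = float(np.min(thresholds[np.isclose(mccs, best_mcc, rtol=0, atol=1e-15)]))
    report = metrics_from_confusion(confusion_from_scores(scores, labels, best_t))
    report.threshold = best_t
    report.auc = roc_auc(scores, labels).area
    return best_t, report


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC.

    The area equals the Mann-Whitney statistic (ties counted 1/2) and is
    cross-computed as the trapezoidal area under the threshold-swept curve;
    the two must agree to 1e-12.
    """
    scores, labels = _check_aligned(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required for ROC analysis")
    ranks = stats.rankdata(scores)
    auc_mw = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    auc_trap = float(np.trapezoid(tpr, fpr))
    if abs(auc_mw - auc_trap) > 1e-12:
        raise AssertionError(
            f"rank AUC {auc_mw!r} and trapezoidal AUC {auc_trap!r} disagree"
        )
    return RocCurve(fpr=fpr, tpr=tpr, area=float(auc_mw))


def confusion_from_residue_sets(
    predicted: set[str], true: set[str], universe: set[str]
) -> ConfusionMatrix:
    """Confusion counts from residue-identifier sets (e.g. {"Gly18", ...})."""
    outside = (set(predicted) | set(true)) - set(universe)
    if outside:
        raise ContractError(f"residues outside the chain universe: {sorted(outside)}")
    tp = len(set(predicted) & set(true))
    fp = len(set(predicted) - set(true))
    fn = len(set(true) - set(predicted))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=len(universe) - tp - fp - fn)


def per_aa_recognition_rates(
    records: Sequence[ProteinRecord], calls: Sequence[np.ndarray]
) -> pd.DataFrame:
    """Recognition rate per amino acid among true binding residues.

    rate(aa) = correctly predicted binding residues of type aa
               / all true binding residues of type aa.
    Types absent from the binding sites get NaN (undefined), not 0.
    """
    if len(records) != len(calls):
        raise ContractError(f"{len(records)} records vs {len(calls)} call vectors")
    n_binding = {aa: 0 for aa in AMINO_ACIDS}
    n_hit = {aa: 0 for aa in AMINO_ACIDS}
    for rec, c in zip(records, calls):
        if rec.labels is None:
            raise ContractError(f"record {rec.chain_id!r} has no labels")
        c = np.asarray(c).astype(int)
        if c.shape != (len(rec),):
            raise ContractError(f"record {rec.chain_id!r}: call vector misaligned")
        for aa, y, yhat in zip(rec.sequence, rec.labels, c):
            if y == 1 and aa in n_binding:
                n_binding[aa] += 1
                n_hit[aa] += int(yhat == 1)
    rows = []
    for aa in AMINO_ACIDS:
        rate = n_hit[aa] / n_binding[aa] if n_binding[aa] else float("nan")
        rows.append({"amino_acid": aa, "n_binding": n_binding[aa],
                     "n_recognized": n_hit[aa], "recognition_rate": rate})
    return pd.DataFrame(rows).set_index("amino_acid")


@dataclass
class CompositionComparison:
    table: pd.DataFrame  # per-AA percentage shares in true vs predicted sets
    pearson_r: float
    pearson_p: float
    mae: float  # mean absolute difference in percentage points over the 20 types

    def summary(self) -> str:
        return (f"composition concordance: Pearson r {self.pearson_r:.2f} "
                f"(p {self.pearson_p:.2g}), MAE {self.mae:.2f} percentage points")


def _composition(residues: Sequence[str]) -> np.ndarray:
    counts = np.array([sum(1 for r in residues if r == aa) for aa in AMINO_ACIDS], float)
    return 100.0 * counts / counts.sum()


def composition_comparison(
    true_binding: Sequence[str], predicted_binding: Sequence[str]
) -> CompositionComparison:
    """Compare amino-acid composition (%) of true vs predicted binding residues.

    Inputs are the amino-acid types (one-letter) of the residues in each set.
    Pearson r is computed across the 20 shares; MAE is in percentage points.
    """
    if len(true_binding) == 0 or len(predicted_binding) == 0:
        raise DataError("both residue sets must be non-empty")
    a = _composition(true_binding)
    b = _composition(predicted_binding)
    r, p = stats.pearsonr(a, b)
    table = pd.DataFrame(
        {"true_pct": a, "predicted_pct": b}, index=list(AMINO_ACIDS)
    )
    return CompositionComparison(
        table=table, pearson_r=float(r), pearson_p=float(p),
        mae=float(np.mean(np.abs(a - b))),
    )


def evaluate_scores(scores, labels) -> MetricsReport:
    """Full report at the MCC-optimal threshold, with AUC."""
    _, report = optimal_threshold_by_mcc(scores, labels)
    return report
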
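"""Weighted fusion of the two classifiers' residue probabilities.

The final score is the convex combination w * p_transformer +
(1 - w) * p_dqn. The weight is selected by cross-validation: for every
weight on a grid over [0, 1] (including both endpoints), fused scores are
evaluated per fold at the MCC-optimal threshold, and the weight with the
highest mean MCC wins; ties break towards higher mean AUC, then towards
the smaller weight. Because the grid contains the endpoints, the selected
weight's selection-fold MCC can never fall below either base classifier's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError
from .evaluation import optimal_threshold_by_mcc, roc_auc

__all__ = ["EnsembleSpec", "fuse_probabilities", "optimize_weight",
           "WeightedEnsemble", "EnsembleResults"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Weight-search settings: grid step, folds, selection metric (MCC)."""

    grid_step: float = 0.05
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.grid_step <= 0.5:
            raise ConfigError("grid_step must be in (0, 0.5]")
        if self.cv_folds < 2:
            raise ConfigError("need at least 2 folds")

    @property
    def grid(self) -> np.ndarray:
        """Weight grid over [0, 1]; both endpoints are always included."""
        n = int(round(1.0 / self.grid_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def fuse_probabilities(p_transformer, p_dqn, w: float) -> np.ndarray:
    """Elementwise convex combination w * p_t + (1 - w) * p_d."""
    p_t = np.asarray(p_transformer, dtype=float)
    p_d = np.asarray(p_dqn, dtype=float)
    if p_t.shape != p_d.shape:
        raise ContractError(f"score shapes differ: {p_t.shape} vs {p_d.shape}")
    if not 0.0 <= w <= 1.0:
        raise ContractError(f"weight {w} outside [0, 1]")
    if w == 1.0:
        return p_t.copy()
    if w == 0.0:
        return p_d.copy()
    return w * p_t + (1.0 - w) * p_d


def optimize_weight(
    fold_scores: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    spec: EnsembleSpec | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the fusion weight on per-fold (p_t, p_d, labels) triples.

    Returns the selected weight and the full per-weight table of mean MCC
    and AUC across folds (for plotting the weight-sweep curves). Folds with
    a single label class are skipped with a warning.
    """
    spec = spec or EnsembleSpec()
    if len(fold_scores) < 2:
        raise DataError("need at least two folds to select the weight")
    usable = []
    for i, (p_t, p_d, y) in enumerate(fold_scores):
        y = np.asarray(y).astype(int)
        if y.min() == y.max():
            warnings.warn(f"fold {i} has a single class; skipped", stacklevel=2)
            continue
        usable.append((np.asarray(p_t, float), np.asarray(p_d, float), y))
    if not usable:
        raise DataError("all folds were single-class; cannot select a weight")

    rows = []
    for w in spec.grid:
        mccs, aucs = [], []
        for p_t, p_d, y in usable:
            fused = fuse_probabilities(p_t, p_d, float(w))
            _, report = optimal_threshold_by_mcc(fused, y)
            mccs.append(report.mcc)
            aucs.append(report.auc)
        rows.append({"weight": float(w), "mean_mcc": float(np.mean(mccs)),
                     "mean_auc": float(np.mean(aucs))})
    table = pd.DataFrame(rows)
    # max mean MCC; ties -> higher mean AUC, then smaller weight
    order = table.sort_values(
        by=["mean_mcc", "mean_auc", "weight"], ascending=[False, False, True],
        kind="stable",
    )
    return float(order.iloc[0]["weight"]), table


class EnsembleResults:
    """Selected fusion weight with its cross-validation sweep table."""

    def __init__(self, weight: float, table: pd.DataFrame, spec: EnsembleSpec):
        self.weight = weight
        self.table = table
        self.spec = spec

    def fuse(self, p_transformer, p_dqn) -> np.ndarray:
        return fuse_probabilities(p_transformer, p_dqn, self.weight)

    def summary(self) -> str:
        at = self.table.loc[self.table["weight"] == self.weight].iloc[0]
        return (
            "Weighted probability ensemble\n"
            f"  transformer weight: {self.weight:.2f}  (DQN weight "
            f"{1 - self.weight:.2f})\n"
            f"  selection-fold mean MCC {at['mean_mcc']:.3f}, "
            f"mean AUC {at['mean_auc']:.3f}"
        )


class WeightedEnsemble:
    """Model object: per-fold base-classifier scores -> fitted fusion weight."""

    def __init__(self, fold_scores, spec: EnsembleSpec | None = None):
        self.fold_scores = fold_scores
        self.spec = spec or EnsembleSpec()

    def fit(self) -> EnsembleResults:
        weight, table = optimize_weight(self.fold_scores, self.spec)
        return EnsembleResults(weight=weight, table=table, spec=self.spec)
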
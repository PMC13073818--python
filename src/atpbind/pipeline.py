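"""End-to-end orchestration: cross-validation, the window-size and
weight-sweep experiments, and the full train -> fuse -> evaluate pipeline.

Fold assignment is a deterministic hash of chain id and seed, so folds are
stable across re-runs and insertion order. All stochastic components derive
their seeds from one global seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dqn import DQNClassifier, DQNConfig
from .ensemble import EnsembleSpec, WeightedEnsemble, fuse_probabilities
from .errors import DataError
from .evaluation import optimal_threshold_by_mcc
from .synthetic import SyntheticDataset
from .transformer import LocalGlobalTransformer, TransformerConfig

__all__ = [
    "ExperimentConfig",
    "assign_folds",
    "cross_validate",
    "window_sweep",
    "run_full_pipeline",
    "PipelineReport",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Seeds and sub-configurations for a full experiment."""

    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    dqn: DQNConfig = field(default_factory=DQNConfig)
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    cv_folds: int = 5
    seed: int = 0

    def derived(self) -> "ExperimentConfig":
        """Push the global seed into every stochastic component deterministically."""
        seeds = np.random.SeedSequence(self.seed).generate_state(3) % (2**31)
        return replace(
            self,
            transformer=replace(self.transformer, seed=int(seeds[0])),
            dqn=replace(self.dqn, seed=int(seeds[1])),
            ensemble=replace(self.ensemble, seed=int(seeds[2])),
        )


def assign_folds(chain_ids: Sequence[str], n_folds: int, seed: int) -> dict[str, int]:
    """Deterministic fold per chain from a hash of chain id and seed.

    Chains are ranked by their hash and dealt round-robin, which keeps the
    folds balanced in chain count while staying independent of input order.
    """
    ids = list(dict.fromkeys(chain_ids))
    if len(ids) < n_folds:
        raise DataError(f"{len(ids)} chains < {n_folds} folds")
    def h(cid: str) -> int:
        return int.from_bytes(
            hashlib.sha256(f"{cid}:{seed}".encode()).digest()[:8], "big"
        )
    ranked = sorted(ids, key=h)
    return {cid: i % n_folds for i, cid in enumerate(ranked)}


def _fold_masks(groups: np.ndarray, folds: dict[str, int], n_folds: int):
    fold_of = np.array([folds[g] for g in groups])
    return [(fold_of != k, fold_of == k) for k in range(n_folds)]


def cross_validate(
    dataset: SyntheticDataset,
    transformer_config: TransformerConfig,
    dqn_config: DQNConfig,
    n_folds: int = 5,
    seed: int = 0,
    models: Sequence[str] = ("transformer", "dqn"),
) -> pd.DataFrame:
    """Chain-level k-fold cross-validation of both base classifiers.

    Returns one row per (fold, model) with ACC/Sen/Spe/MCC/AUC on the held
    fold, plus a mean row per model.
    """
    X, y, groups = dataset.X, dataset.y, dataset.groups
    folds = assign_folds(groups, n_folds, seed)
    rows = []
    for k, (train_mask, test_mask) in enumerate(_fold_masks(groups, folds, n_folds)):
        for model in models:
            if model == "transformer":
                fit = LocalGlobalTransformer(
                    X[train_mask], y[train_mask], groups=groups[train_mask],
                    config=replace(transformer_config, seed=transformer_config.seed + k),
                ).fit()
            elif model == "dqn":
                fit = DQNClassifier(
                    X[train_mask], y[train_mask], groups=groups[train_mask],
                    config=replace(dqn_config, seed=dqn_config.seed + k),
                ).fit()
            else:
                raise ValueError(f"unknown model {model!r}")
            scores = fit.predict_proba(X[test_mask])
            _, rep = optimal_threshold_by_mcc(scores, y[test_mask])
            rows.append({"fold": k, "model": model, "acc": rep.acc, "sen": rep.sen,
                         "spe": rep.spe, "mcc": rep.mcc, "auc": rep.auc})
    table = pd.DataFrame(rows)
    means = (table.groupby("model")[["acc", "sen", "spe", "mcc", "auc"]]
             .mean().reset_index())
    means.insert(0, "fold", "mean")
    return pd.concat([table, means], ignore_index=True)


def window_sweep(
    dataset: SyntheticDataset,
    base_config: TransformerConfig,
    windows: Sequence[int] = (8, 16, 24, 32, 48, 64),
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Local-window-size experiment: CV MCC/AUC per candidate window.

    Every candidate must divide the projected width; the whole sweep is
    reproducible from one seed.
    """
    rows = []
    for w in windows:
        cfg = replace(base_config, window=int(w))
        table = cross_validate(dataset, cfg, DQNConfig(), n_folds=n_folds,
                               seed=seed, models=("transformer",))
        mean = table[table["fold"] == "mean"].iloc[0]
        rows.append({"window": int(w), "mean_mcc": float(mean["mcc"]),
                     "mean_auc": float(mean["auc"])})
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    """Outputs of a full train -> ensemble -> independent-test run."""

    weight: float
    weight_table: pd.DataFrame
    test_metrics: dict[str, dict[str, float]]  # per model: acc/sen/spe/mcc/auc
    manifest: dict

    def summary(self) -> str:
        lines = [f"ensemble weight (transformer): {self.weight:.2f}"]
        for model, m in self.test_metrics.items():
            lines.append(
                f"  {model}: ACC {m['acc']:.3f} Sen {m['sen']:.3f} "
                f"Spe {m['spe']:.3f} MCC {m['mcc']:.3f} AUC {m['auc']:.3f}"
            )
        return "\n".join(lines)


def run_full_pipeline(
    train: SyntheticDataset,
    test: SyntheticDataset,
    config: ExperimentConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Train both classifiers, select the fusion weight by training-set CV,
    fuse on the independent test set, and evaluate all three predictors."""
    config = (config or ExperimentConfig()).derived()
    t_fit = LocalGlobalTransformer.from_dataset(train, config.transformer).fit()
    d_fit = DQNClassifier.from_dataset(train, config.dqn).fit()

    # weight selection on training-set CV folds (models trained above;
    # scores on held-out chains of the training set)
    folds = assign_folds(train.groups, config.cv_folds, config.seed)
    fold_scores = []
    for k in range(config.cv_folds):
        mask = np.array([folds[g] == k for g in train.groups])
        fold_scores.append((
            t_fit.predict_proba(train.X[mask]),
            d_fit.predict_proba(train.X[mask]),
            train.y[mask],
        ))
    ens = WeightedEnsemble(fold_scores, config.ensemble).fit()

    p_t = t_fit.predict_proba(test.X)
    p_d = d_fit.predict_proba(test.X)
    p_e = ens.fuse(p_t, p_d)
    metrics = {}
    for name, scores in (("transformer", p_t), ("dqn", p_d), ("ensemble", p_e)):
        _, rep = optimal_threshold_by_mcc(scores, test.y)
        metrics[name] = {"acc": rep.acc, "sen": rep.sen, "spe": rep.spe,
                         "mcc": rep.mcc, "auc": rep.auc,
                         "threshold": rep.threshold}

    manifest = {
        "seed": config.seed,
        "cv_folds": config.cv_folds,
        "transformer_config": {k: _jsonable(v) for k, v in
                               vars(config.transformer).items()},
        "dqn_config": {k: _jsonable(v) for k, v in vars(config.dqn).items()},
        "ensemble_spec": {k: _jsonable(v) for k, v in vars(config.ensemble).items()},
        "weight": ens.weight,
        "n_train_residues": int(train.y.size),
        "n_test_residues": int(test.y.size),
        "score_hashes": {
            "transformer": hashlib.sha256(p_t.tobytes()).hexdigest()[:16],
            "dqn": hashlib.sha256(p_d.tobytes()).hexdigest()[:16],
            "ensemble": hashlib.sha256(p_e.tobytes()).hexdigest()[:16],
        },
    }
    report = PipelineReport(weight=ens.weight, weight_table=ens.table,
                            test_metrics=metrics, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ens.table.to_csv(out / "weight_sweep.tsv", sep="\t", index=False)
        pd.DataFrame(metrics).T.to_csv(out / "test_metrics.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    return v
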
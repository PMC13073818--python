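"""Save/load fitted classifiers as .npz archives (parameters + config)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .dqn import DQNClassifier, DQNConfig, DQNResults, QNetwork
from .errors import IntegrityError
from .features import FeatureStandardizer
from .transformer import (LocalGlobalTransformer, TransformerConfig,
                          TransformerNetwork, TransformerResults)

__all__ = ["save_model", "load_model"]

_KINDS = {"transformer", "dqn"}


def save_model(results, path: str | Path) -> None:
    """Persist a fitted TransformerResults or DQNResults."""
    if isinstance(results, TransformerResults):
        kind = "transformer"
    elif isinstance(results, DQNResults):
        kind = "dqn"
    else:
        raise TypeError(f"cannot persist {type(results).__name__}")
    payload = {f"param::{k}": v for k, v in results.network.state_dict().items()}
    if results.standardizer is not None:
        payload["std::mean"] = results.standardizer.mean_
        payload["std::scale"] = results.standardizer.scale_
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(results.config).items()}
    payload["meta"] = np.frombuffer(
        json.dumps({"kind": kind, "config": cfg}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; returns a Results object."""
    with np.load(path) as z:
        try:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
        except (KeyError, ValueError) as exc:
            raise IntegrityError(f"{path}: not an atpbind model file") from exc
        kind = meta["kind"]
        if kind not in _KINDS:
            raise IntegrityError(f"{path}: unknown model kind {kind!r}")
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
        std = None
        if "std::mean" in z.files:
            std = FeatureStandardizer()
            std.mean_ = z["std::mean"]
            std.scale_ = z["std::scale"]
    rng = np.random.default_rng(0)  # parameters are overwritten below
    if kind == "transformer":
        cfg = TransformerConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                   for k, v in meta["config"].items()})
        net = TransformerNetwork(cfg, rng)
        net.load_state_dict(state)
        import pandas as pd
        return TransformerResults(network=net, standardizer=std,
                                  history=pd.DataFrame(), best_epoch=-1,
                                  val_report=None, config=cfg)
    cfg = DQNConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in meta["config"].items()})
    net = QNetwork(cfg, rng)
    net.load_state_dict(state)
    import pandas as pd
    return DQNResults(network=net, standardizer=std, history=pd.DataFrame(),
                      train_accuracy=float("nan"), validation=None, config=cfg)
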
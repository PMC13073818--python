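"""Local-global dual-attention residue classifier.

One residue's embedding (1280 values from the protein language model, or
whatever width the feature source provides) is projected to a 384-wide
feature vector that is treated as a sequence of 384 scalar positions. Each
position is lifted to a small token, and two multi-head self-attention
branches run over the tokens: a *global* branch attending across all
positions and a *local* branch restricted to non-overlapping windows of
consecutive positions. The branches are fused by a single learnable convex
weight, collapsed back to a 384-dim latent, and classified through a
dynamic-weight head (a sigmoid-gated feature mask followed by a sigmoid
output unit). Training combines focal loss, a differentiable MCC penalty,
and a supervised contrastive term on an L2-normalised 256-dim projection,
with positive-class oversampling and mild augmentation.

Attention operates over the projected feature positions of a single
residue, not across residues of a chain; every candidate local window size
divides 384 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError
from .evaluation import optimal_threshold_by_mcc
from .features import FeatureStandardizer
from .nn import Adam, LayerNorm, Linear, Module, MultiHeadAttention, Tensor, as_tensor
from .nn.layers import dropout as _dropout
from .nn.optim import cosine_annealing

__all__ = [
    "TransformerConfig",
    "TransformerNetwork",
    "BatchLossReport",
    "focal_loss",
    "soft_mcc_penalty",
    "contrastive_loss",
    "hybrid_loss",
    "LocalGlobalTransformer",
    "TransformerResults",
]

PROB_CLIP = 1e-7  # probability clipping bound for all loss computations


@dataclass(frozen=True)
class TransformerConfig:
    """Hyperparameters of the dual-attention classifier.

    Defaults follow the published architecture: 384 hidden units, local
    window 32, 8 attention heads, dropout 0.15, focal loss gamma 2.0 /
    alpha 0.2, MCC penalty weight 0.7, 256-dim contrastive projection.
    The window-size experiment grid is {8, 16, 24, 32, 48, 64}; each value
    divides 384.
    """

    in_dim: int = 1280
    proj_dim: int = 384
    token_dim: int = 32
    heads: int = 8
    window: int = 32
    dropout: float = 0.15
    contrastive_dim: int = 256
    temperature: float = 0.1
    contrastive_weight: float = 0.1
    focal_gamma: float = 2.0
    focal_alpha: float = 0.2
    mcc_penalty_weight: float = 0.7
    oversample_frac: float = 0.25
    noise_sd: float = 0.01
    mask_fraction: float = 0.05
    lr_init: float = 1e-3
    lr_final: float = 1e-5
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 256
    val_fraction: float = 0.2
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.proj_dim % self.window:
            raise ConfigError(
                f"window {self.window} must divide proj_dim {self.proj_dim}"
            )
        if self.token_dim % self.heads:
            raise ConfigError(
                f"heads {self.heads} must divide token_dim {self.token_dim}"
            )
        for name in ("dropout", "oversample_frac", "mask_fraction", "val_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} {v} outside [0, 1]")
        if self.focal_gamma < 0:
            raise ConfigError("focal_gamma must be >= 0")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")


@dataclass
class BatchLossReport:
    """Components of one batch's training objective.

    ``mcc_penalty`` is already scaled by the configured penalty weight;
    ``contrastive`` is the raw contrastive value, scaled into ``total``
    by ``contrastive_weight``.
    """

    focal: float
    mcc_penalty: float
    contrastive: float
    total: float


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def focal_loss(p, y, gamma: float = 2.0, alpha: float = 0.2) -> Tensor:
    """Mean focal loss: -alpha_t (1 - p_t)^gamma log(p_t).

    ``alpha`` weights the positive class (alpha_t = alpha for y=1 and
    1-alpha for y=0); ``p_t`` is the predicted probability of the true
    class, clipped to [1e-7, 1 - 1e-7].
    """
    p = as_tensor(p)
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=float).ravel()
    if not np.isin(y_arr, (0.0, 1.0)).all():
        raise ContractError("labels must be binary 0/1")
    y_t = Tensor(y_arr)
    p = p.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    p_t = p * y_t + (1.0 - p) * (1.0 - y_t)
    alpha_t = alpha * y_t + (1.0 - alpha) * (1.0 - y_t)
    return (-1.0 * alpha_t * (1.0 - p_t) ** gamma * p_t.log()).mean()


def soft_mcc_penalty(p, y, weight: float = 0.7, eps: float = 1e-7) -> Tensor:
    """Differentiable MCC penalty weight * (1 - max(MCC, 0)).

    MCC is evaluated on probabilistic confusion counts TP = sum(p*y),
    FP = sum(p*(1-y)), FN = sum((1-p)*y), TN = sum((1-p)*(1-y)) with an
    epsilon-protected denominator, so an all-one-class batch yields MCC 0
    (penalty = weight) rather than a division failure.
    """
    p = as_tensor(p)
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=float).ravel()
    if not np.isin(y_arr, (0.0, 1.0)).all():
        raise ContractError("labels must be binary 0/1")
    y_t = Tensor(y_arr)
    p = p.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    tp = (p * y_t).sum()
    fp = (p * (1.0 - y_t)).sum()
    fn = ((1.0 - p) * y_t).sum()
    tn = ((1.0 - p) * (1.0 - y_t)).sum()
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) + eps) ** 0.5
    mcc = (tp * tn - fp * fn) / denom
    return weight * (1.0 - mcc.relu())


def contrastive_loss(projections, y, temperature: float = 0.1, eps: float = 1e-8) -> Tensor:
    """Supervised contrastive loss over L2-normalised projections.

    For each anchor with at least one same-class partner in the batch, the
    loss is the mean over those partners of -log(exp(sim/tau) / sum over all
    non-anchor entries of exp(sim/tau)); anchors without a positive partner
    are skipped. Per-anchor maximum similarities are subtracted (detached)
    and an epsilon added inside the log for numerical stability.
    """
    z = as_tensor(projections)
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y).ravel().astype(int)
    b = z.shape[0]
    if b != y_arr.size:
        raise ContractError(f"{b} projections vs {y_arr.size} labels")
    norms = np.linalg.norm(z.data, axis=1)
    if np.any(norms < 1e-12):
        raise ContractError("zero-norm projection passed to contrastive loss")
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)
    not_self = 1.0 - np.eye(b)
    pos_mask = ((y_arr[:, None] == y_arr[None, :]) & ~np.eye(b, dtype=bool)).astype(float)
    n_pos = pos_mask.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        raise DataError("no anchor has a same-class partner in the batch")
    # detached per-row max over non-self entries
    masked = np.where(not_self > 0, sim.data, -np.inf)
    row_max = Tensor(masked.max(axis=1, keepdims=True))
    shifted = sim - row_max
    exp_ = shifted.exp() * Tensor(not_self)
    log_denom = (exp_.sum(axis=1, keepdims=True) + eps).log()
    log_prob = shifted - log_denom
    per_anchor = (log_prob * Tensor(pos_mask)).sum(axis=1) / Tensor(np.maximum(n_pos, 1.0))
    picked = per_anchor * Tensor(valid.astype(float))
    return -1.0 * picked.sum() / float(valid.sum())


def normalize_l2(z: Tensor, eps: float = 1e-12) -> Tensor:
    return z / (((z**2).sum(axis=-1, keepdims=True) + eps) ** 0.5)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class TransformerNetwork(Module):
    """All trainable parameters of the dual-attention classifier."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        self.proj = self.add_module("proj", Linear(rng, c.in_dim, c.proj_dim))
        self.norm = self.add_module("norm", LayerNorm(c.proj_dim))
        self.w_lift = self.add_param("w_lift", rng.normal(0.0, 0.5, size=(1, c.token_dim)))
        self.b_lift = self.add_param("b_lift", np.zeros(c.token_dim))
        self.pos_emb = self.add_param(
            "pos_emb", rng.normal(0.0, 0.02, size=(c.proj_dim, c.token_dim))
        )
        self.attn_global = self.add_module(
            "attn_global", MultiHeadAttention(rng, c.token_dim, c.heads)
        )
        self.attn_local = self.add_module(
            "attn_local", MultiHeadAttention(rng, c.token_dim, c.heads)
        )
        self.alpha_fuse = self.add_param("alpha_fuse", np.zeros(1))
        self.collapse = self.add_module("collapse", Linear(rng, c.token_dim, 1))
        self.contrastive_proj = self.add_module(
            "contrastive_proj", Linear(rng, c.proj_dim, c.contrastive_dim)
        )
        self.weight_head = self.add_module(
            "weight_head", Linear(rng, c.proj_dim, c.proj_dim)
        )
        self.out = self.add_module("out", Linear(rng, c.proj_dim, 1))
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # -- stages ------------------------------------------------------------
    def project_input(self, x, training: bool = False) -> Tensor:
        """Affine projection to proj_dim, layer normalisation, dropout."""
        x = as_tensor(x)
        if x.shape[-1] != self.config.in_dim:
            raise ContractError(
                f"input dim {x.shape[-1]} != configured {self.config.in_dim}"
            )
        z = self.norm(self.proj(x))
        return _dropout(z, self.config.dropout, self._dropout_rng, training)

    def _lift(self, z: Tensor) -> Tensor:
        b, t = z.shape
        tokens = z.reshape(b, t, 1) @ self.w_lift + self.b_lift + self.pos_emb
        return tokens

    def dual_attention(self, z: Tensor) -> Tensor:
        """Fused local/global attention over the projected feature positions."""
        c = self.config
        b, t = z.shape
        if t != c.proj_dim:
            raise ContractError(f"expected {c.proj_dim} features, got {t}")
        tokens = self._lift(z)
        g = self.attn_global(tokens)
        nw = t // c.window
        local_in = tokens.reshape(b * nw, c.window, c.token_dim)
        l = self.attn_local(local_in).reshape(b, t, c.token_dim)
        w = self.alpha_fuse.sigmoid()
        fused_tokens = g * w + l * (1.0 - w)
        return self.collapse(fused_tokens).reshape(b, t)

    def latent(self, x, training: bool = False) -> Tensor:
        return self.dual_attention(self.project_input(x, training=training))

    def contrastive_projection(self, latent: Tensor) -> Tensor:
        return normalize_l2(self.contrastive_proj(latent))

    def head(self, latent: Tensor) -> Tensor:
        weights = self.weight_head(latent).sigmoid()
        logits = self.out(weights * latent)
        return logits.sigmoid().reshape(-1)

    def forward(self, x, training: bool = False) -> Tensor:
        """Per-residue binding probability in (0, 1)."""
        self.check_finite()
        return self.head(self.latent(x, training=training))

    def predict_proba(self, x: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Deterministic inference-mode probabilities, chunked over rows."""
        from .nn.autodiff import no_grad

        x = np.asarray(x, dtype=np.float64)
        if not len(x):
            return np.empty(0)
        with no_grad():
            return np.concatenate(
                [self.forward(x[i : i + chunk]).data for i in range(0, len(x), chunk)]
            )


def hybrid_loss(
    probs: Tensor, projections: Tensor, y: np.ndarray, config: TransformerConfig
) -> tuple[Tensor, BatchLossReport]:
    """Total objective: focal + weighted MCC penalty + weighted contrastive."""
    f = focal_loss(probs, y, gamma=config.focal_gamma, alpha=config.focal_alpha)
    m = soft_mcc_penalty(probs, y, weight=config.mcc_penalty_weight)
    if config.contrastive_weight > 0:
        c = contrastive_loss(projections, y, temperature=config.temperature)
    else:
        c = Tensor(0.0)
    total = f + m + config.contrastive_weight * c
    report = BatchLossReport(
        focal=f.item(), mcc_penalty=m.item(), contrastive=c.item(), total=total.item()
    )
    return total, report


# ---------------------------------------------------------------------------
# model / results (fit interface)
# ---------------------------------------------------------------------------

def split_chains(
    groups: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chain-level train/validation split; returns boolean row masks."""
    chains = np.unique(groups)
    if chains.size < 2:
        raise DataError("need at least two chains for a chain-level split")
    perm = rng.permutation(chains)
    n_val = max(1, int(round(val_fraction * chains.size)))
    val_chains = set(perm[:n_val].tolist())
    val_mask = np.isin(groups, list(val_chains))
    return ~val_mask, val_mask


class _OversamplingBatcher:
    """Draws batches with a fixed positive fraction, cycling negatives."""

    def __init__(self, y: np.ndarray, batch_size: int, pos_frac: float,
                 rng: np.random.Generator):
        self.pos_idx = np.flatnonzero(y == 1)
        self.neg_idx = np.flatnonzero(y == 0)
        if self.pos_idx.size == 0:
            raise DataError("no positive residues in the training data")
        self.batch_size = batch_size
        self.n_pos = max(1, int(round(batch_size * pos_frac)))
        self.n_neg = batch_size - self.n_pos
        self.rng = rng

    def epoch(self, n_batches: int):
        neg_pool = self.rng.permutation(self.neg_idx)
        cursor = 0
        for _ in range(n_batches):
            pos = self.rng.choice(self.pos_idx, size=self.n_pos, replace=True)
            if cursor + self.n_neg > neg_pool.size:
                neg_pool = self.rng.permutation(self.neg_idx)
                cursor = 0
            neg = neg_pool[cursor : cursor + self.n_neg]
            cursor += self.n_neg
            yield np.concatenate([pos, neg])


class TransformerResults:
    """Fitted dual-attention classifier with its training history."""

    def __init__(self, network, standardizer, history, best_epoch, val_report,
                 config):
        self.network = network
        self.standardizer = standardizer
        self.history = history
        self.best_epoch = best_epoch
        self.validation = val_report
        self.config = config

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.standardizer is not None:
            x = self.standardizer.transform(x)
        return self.network.predict_proba(x)

    def summary(self) -> str:
        lines = [
            "Local-global dual-attention classifier",
            f"  epochs run: {len(self.history)} (best epoch {self.best_epoch})",
            f"  validation: {self.validation.summary()}",
            f"  window {self.config.window}, proj_dim {self.config.proj_dim}, "
            f"heads {self.config.heads}",
        ]
        return "\n".join(lines)


class LocalGlobalTransformer:
    """Model object: per-residue features + labels -> fitted classifier.

    Parameters
    ----------
    X : (n_residues, dim) feature matrix
    y : (n_residues,) binary labels (1 = ATP-binding)
    groups : per-residue chain identifiers for the chain-level validation
        split; if omitted, residues are grouped into pseudo-chains of 100.
    config : TransformerConfig
    """

    def __init__(self, X, y, groups=None, config: TransformerConfig | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y).astype(int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ContractError("X must be (n, dim) aligned with y")
        if groups is None:
            groups = np.arange(self.y.size) // 100
        self.groups = np.asarray(groups)
        cfg = config or TransformerConfig()
        if cfg.in_dim != self.X.shape[1]:
            cfg = replace(cfg, in_dim=self.X.shape[1])
        self.config = cfg

    @classmethod
    def from_dataset(cls, dataset, config: TransformerConfig | None = None):
        """Build from a SyntheticDataset-like object with X, y, groups."""
        return cls(dataset.X, dataset.y, groups=dataset.groups, config=config)

    def fit(self, verbose: bool = False) -> TransformerResults:
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        rng_split, rng_init, rng_batch, rng_aug = (
            np.random.default_rng(s) for s in ss.spawn(4)
        )
        train_mask, val_mask = split_chains(self.groups, cfg.val_fraction, rng_split)
        x_train, y_train = self.X[train_mask], self.y[train_mask]
        x_val, y_val = self.X[val_mask], self.y[val_mask]
        if y_train.sum() == 0:
            raise DataError("no positive residues in the training split")

        standardizer = None
        if cfg.standardize:
            standardizer = FeatureStandardizer().fit(x_train)
            x_train = standardizer.transform(x_train)
            x_val = standardizer.transform(x_val)

        net = TransformerNetwork(cfg, rng_init)
        opt = Adam(net.parameters(), lr=cfg.lr_init)
        batcher = _OversamplingBatcher(y_train, cfg.batch_size, cfg.oversample_frac,
                                       rng_batch)
        n_batches = max(1, len(y_train) // cfg.batch_size)

        history_rows = []
        best_mcc, best_state, best_epoch = -np.inf, None, -1
        patience_left = cfg.patience
        for epoch in range(cfg.max_epochs):
            opt.lr = cosine_annealing(cfg.lr_init, cfg.lr_final, epoch, cfg.max_epochs)
            sums = np.zeros(4)
            for idx in batcher.epoch(n_batches):
                xb = x_train[idx].copy()
                yb = y_train[idx]
                # mild augmentation: Gaussian jitter and random feature masking
                xb += rng_aug.normal(0.0, cfg.noise_sd, size=xb.shape)
                if cfg.mask_fraction > 0:
                    xb[rng_aug.random(xb.shape) < cfg.mask_fraction] = 0.0
                z = net.project_input(xb, training=True)
                latent = net.dual_attention(z)
                probs = net.head(latent)
                proj = net.contrastive_projection(latent)
                loss, report = hybrid_loss(probs, proj, yb, cfg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                sums += (report.focal, report.mcc_penalty, report.contrastive,
                         report.total)
            focal_m, mcc_m, con_m, total_m = sums / n_batches

            val_scores = net.predict_proba(x_val)
            if y_val.min() == y_val.max():
                raise DataError("validation split contains a single class")
            _, val_report = optimal_threshold_by_mcc(val_scores, y_val)
            row = {
                "epoch": epoch, "lr": opt.lr, "focal": focal_m,
                "mcc_penalty": mcc_m, "contrastive": con_m, "total": total_m,
                "val_mcc": val_report.mcc, "val_auc": val_report.auc,
            }
            history_rows.append(row)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: total {total_m:.4f} "
                      f"val MCC {val_report.mcc:.3f} AUC {val_report.auc:.3f}")
            if val_report.mcc > best_mcc:
                best_mcc = val_report.mcc
                best_state = net.state_dict()
                best_epoch = epoch
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

        net.load_state_dict(best_state)
        final_scores = net.predict_proba(x_val)
        _, final_report = optimal_threshold_by_mcc(final_scores, y_val)
        return TransformerResults(
            network=net, standardizer=standardizer,
            history=pd.DataFrame(history_rows), best_epoch=best_epoch,
            val_report=final_report, config=cfg,
        )
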
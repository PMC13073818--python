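"""Dual-attention classifier: architecture contracts, losses vs independent
oracles, and training behaviour."""

import math
from dataclasses import replace

import numpy as np
import pytest

from atpbind import SynthConfig, generate_dataset
from atpbind.errors import ConfigError, ContractError, DataError
from atpbind.nn import MultiHeadAttention, Tensor
from atpbind.transformer import (BatchLossReport, LocalGlobalTransformer,
                                 TransformerConfig, TransformerNetwork,
                                 contrastive_loss, focal_loss, hybrid_loss,
                                 soft_mcc_penalty)

TINY = dict(in_dim=16, proj_dim=16, token_dim=4, heads=2, window=8)


# ---------------------------------------------------------------------------
# independent loss oracles (literal transcriptions of the formulas)
# ---------------------------------------------------------------------------

def focal_oracle(p, y, gamma, alpha):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    total = 0.0
    for pi, yi in zip(p, y):
        p_t = pi if yi == 1 else 1 - pi
        a_t = alpha if yi == 1 else 1 - alpha
        total += -a_t * (1 - p_t) ** gamma * math.log(p_t)
    return total / len(p)


def soft_mcc_oracle(p, y, weight=0.7, eps=1e-7):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    tp = sum(pi * yi for pi, yi in zip(p, y))
    fp = sum(pi * (1 - yi) for pi, yi in zip(p, y))
    fn = sum((1 - pi) * yi for pi, yi in zip(p, y))
    tn = sum((1 - pi) * (1 - yi) for pi, yi in zip(p, y))
    mcc = (tp * tn - fp * fn) / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) + eps)
    return weight * (1 - max(mcc, 0.0))


def contrastive_oracle(z, y, tau):
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    sim = z @ z.T / tau
    b = len(y)
    terms = []
    for i in range(b):
        others = [k for k in range(b) if k != i]
        pos = [j for j in others if y[j] == y[i]]
        if not pos:
            continue
        m = max(sim[i, k] for k in others)
        denom = sum(math.exp(sim[i, k] - m) for k in others)
        terms.append(-np.mean([sim[i, j] - m - math.log(denom + 1e-8) for j in pos]))
    return float(np.mean(terms))


@pytest.mark.parametrize("seed", range(5))
def test_focal_loss_matches_literal_transcription(seed, rng):
    r = np.random.default_rng(seed)
    p = r.random(200)
    y = (r.random(200) < 0.3).astype(int)
    ours = focal_loss(p, y, gamma=2.0, alpha=0.2).item()
    assert abs(ours - focal_oracle(p, y, 2.0, 0.2)) < 1e-10


def test_focal_loss_hand_value_and_reductions():
    # y=1, p=0.9: 0.2 * 0.1^2 * (-ln 0.9)
    assert focal_loss(np.array([0.9]), np.array([1]), 2.0, 0.2).item() == \
        pytest.approx(2.10721031e-4, abs=1e-12)
    # gamma=0, alpha=0.5 reduces to half the binary cross-entropy
    p = np.array([0.7, 0.2, 0.95])
    y = np.array([1, 0, 1])
    bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert focal_loss(p, y, gamma=0.0, alpha=0.5).item() == pytest.approx(0.5 * bce, abs=1e-12)
    # confident-correct limit -> 0
    assert focal_loss(np.array([1.0, 0.0]), np.array([1, 0])).item() < 1e-5


def test_focal_loss_rejects_non_binary_labels():
    with pytest.raises(ContractError):
        focal_loss(np.array([0.5]), np.array([2]))


@pytest.mark.parametrize("seed", range(5))
def test_soft_mcc_penalty_matches_literal_transcription(seed):
    r = np.random.default_rng(seed)
    p = r.random(150)
    y = (r.random(150) < 0.2).astype(int)
    assert abs(soft_mcc_penalty(p, y).item() - soft_mcc_oracle(p, y)) < 1e-10


def test_soft_mcc_penalty_known_cases():
    y = np.array([1, 1, 0, 0])
    assert soft_mcc_penalty(y.astype(float), y).item() == pytest.approx(0.0, abs=1e-5)
    assert soft_mcc_penalty(1.0 - y.astype(float), y).item() == pytest.approx(0.7, abs=1e-5)
    # hand computation: y=[1,0], p=[0.8,0.4] -> soft MCC 0.40825, penalty 0.41423
    assert soft_mcc_penalty(np.array([0.8, 0.4]), np.array([1, 0])).item() == \
        pytest.approx(0.414226, abs=1e-5)
    # all-one-class batch: degenerate MCC treated as 0 -> penalty 0.7, no crash
    assert soft_mcc_penalty(np.array([0.9, 0.8]), np.array([1, 1])).item() == \
        pytest.approx(0.7, abs=1e-3)


def test_soft_mcc_on_hard_calls_matches_integer_confusion(rng):
    from atpbind.evaluation import ConfusionMatrix, metrics_from_confusion
    y = (rng.random(300) < 0.25).astype(int)
    calls = (rng.random(300) < 0.5).astype(float)
    tp = int(np.sum((calls == 1) & (y == 1)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    mcc = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn)).mcc
    expected = 0.7 * (1 - max(mcc, 0.0))
    # hard calls are clipped to [1e-7, 1-1e-7]; agreement to that precision
    assert soft_mcc_penalty(calls, y).item() == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("seed", range(5))
def test_contrastive_loss_matches_brute_force(seed):
    r = np.random.default_rng(seed)
    z = r.normal(size=(12, 8))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    y = (r.random(12) < 0.4).astype(int)
    ours = contrastive_loss(z, y, temperature=0.3).item()
    assert abs(ours - contrastive_oracle(z, y, 0.3)) < 1e-8


def test_contrastive_loss_scale_invariance_and_zero_norm(rng):
    z = rng.normal(size=(6, 8))
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    y = np.array([0, 0, 0, 1, 1, 1])
    a = contrastive_loss(zn, y, 0.2).item()
    b = contrastive_loss(10 * zn / np.linalg.norm(10 * zn, axis=1, keepdims=True), y, 0.2).item()
    assert a == pytest.approx(b, abs=1e-12)
    bad = zn.copy()
    bad[0] = 0.0
    with pytest.raises(ContractError):
        contrastive_loss(bad, y, 0.2)


def test_contrastive_loss_decreases_when_positive_pair_tightens():
    # moving an anchor's same-class partner closer strictly lowers its term
    base = np.array([[1.0, 0.0], [0.8, 0.6], [-1.0, 0.0]])
    closer = np.array([[1.0, 0.0], [0.995, 0.0998], [-1.0, 0.0]])
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    closer /= np.linalg.norm(closer, axis=1, keepdims=True)
    y = np.array([1, 1, 0])
    assert contrastive_loss(closer, y, 0.5).item() < contrastive_loss(base, y, 0.5).item()


def test_hybrid_total_is_reported_weighted_sum(rng):
    p = Tensor(rng.random(40))
    z = rng.normal(size=(40, 8))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    y = (rng.random(40) < 0.3).astype(int)
    cfg = TransformerConfig(**TINY)
    total, rep = hybrid_loss(p, Tensor(z), y, cfg)
    assert rep.total == pytest.approx(
        rep.focal + rep.mcc_penalty + cfg.contrastive_weight * rep.contrastive, abs=1e-12
    )
    # zeroing both auxiliary weights reduces the objective to pure focal loss
    cfg0 = replace(cfg, contrastive_weight=0.0, mcc_penalty_weight=0.0)
    total0, rep0 = hybrid_loss(p, Tensor(z), y, cfg0)
    assert rep0.total == pytest.approx(rep0.focal, abs=1e-12)
    assert rep0.focal == pytest.approx(rep.focal, abs=1e-12)


# ---------------------------------------------------------------------------
# architecture contracts
# ---------------------------------------------------------------------------

def test_config_validates_window_and_heads():
    with pytest.raises(ConfigError, match="window"):
        TransformerConfig(proj_dim=384, window=100)
    with pytest.raises(ConfigError, match="heads"):
        TransformerConfig(token_dim=30, heads=8)
    for w in (8, 16, 24, 32, 48, 64):  # the published candidate grid
        TransformerConfig(window=w)


def test_project_input_shape_dropout_and_degenerate_weights(rng):
    cfg = TransformerConfig(**TINY)
    net = TransformerNetwork(cfg, rng)
    x = rng.normal(size=(3, 16))
    z1 = net.project_input(x)
    z2 = net.project_input(x)
    assert z1.shape == (3, 16)
    np.testing.assert_array_equal(z1.data, z2.data)  # inference is deterministic
    # zero projection weights: layer norm epsilon avoids division blow-up
    net.proj.w.data[:] = 0.0
    net.proj.b.data[:] = 0.0
    z = net.project_input(x)
    assert np.all(np.isfinite(z.data))
    with pytest.raises(ContractError):
        net.project_input(rng.normal(size=(3, 7)))


def test_fusion_saturates_to_global_branch(rng):
    cfg = TransformerConfig(**TINY)
    net = TransformerNetwork(cfg, rng)
    z = net.project_input(rng.normal(size=(4, 16)))
    net.alpha_fuse.data[:] = 50.0  # sigmoid ~ 1 -> pure global
    fused = net.dual_attention(z)
    tokens = net._lift(z)
    g_only = net.collapse(net.attn_global(tokens)).reshape(4, 16)
    np.testing.assert_allclose(fused.data, g_only.data, atol=1e-12)


def test_window_equal_to_width_makes_local_attend_globally(rng):
    cfg = TransformerConfig(**dict(TINY, window=16))  # window == proj_dim
    net = TransformerNetwork(cfg, rng)
    z = net.project_input(rng.normal(size=(2, 16)))
    tokens = net._lift(z)
    local_full = net.attn_local(tokens)  # same support as global attention
    net.alpha_fuse.data[:] = -50.0  # pure local
    fused = net.dual_attention(z)
    np.testing.assert_allclose(
        fused.data, net.collapse(local_full).reshape(2, 16).data, atol=1e-12
    )


def test_attention_is_permutation_equivariant_without_positions(rng):
    mha = MultiHeadAttention(rng, 4, 2)
    x = rng.normal(size=(1, 5, 4))
    perm = rng.permutation(5)
    out = mha(Tensor(x)).data[0]
    out_p = mha(Tensor(x[:, perm])).data[0]
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_forward_outputs_probabilities_and_batching_consistency(rng):
    cfg = TransformerConfig(**TINY)
    net = TransformerNetwork(cfg, rng)
    x = rng.normal(size=(7, 16))
    p = net.forward(x).data
    assert p.shape == (7,)
    assert np.all((p > 0) & (p < 1))
    singles = np.concatenate([net.forward(x[i:i + 1]).data for i in range(7)])
    np.testing.assert_allclose(p, singles, atol=1e-12)
    # zero output weights -> probability exactly sigmoid(bias)
    net.out.w.data[:] = 0.0
    net.out.b.data[:] = 0.3
    np.testing.assert_allclose(net.forward(x).data, 1 / (1 + np.exp(-0.3)), atol=1e-12)


def test_forward_rejects_non_finite_parameters(rng):
    cfg = TransformerConfig(**TINY)
    net = TransformerNetwork(cfg, rng)
    net.out.b.data[:] = np.nan
    with pytest.raises(FloatingPointError):
        net.forward(rng.normal(size=(2, 16)))


# ---------------------------------------------------------------------------
# training behaviour
# ---------------------------------------------------------------------------

def _tiny_train_config(seed=0, **kw):
    return TransformerConfig(
        in_dim=16, proj_dim=16, token_dim=4, heads=2, window=8,
        max_epochs=2, patience=2, batch_size=64, seed=seed, **kw
    )


def test_training_is_reproducible_from_seed(tiny_dataset):
    r1 = LocalGlobalTransformer.from_dataset(tiny_dataset, _tiny_train_config()).fit()
    r2 = LocalGlobalTransformer.from_dataset(tiny_dataset, _tiny_train_config()).fit()
    assert r1.history.equals(r2.history)
    x = tiny_dataset.X[:50]
    np.testing.assert_array_equal(r1.predict_proba(x), r2.predict_proba(x))


def test_training_requires_positive_residues(tiny_dataset):
    y = np.zeros_like(tiny_dataset.y)
    with pytest.raises(DataError):
        LocalGlobalTransformer(tiny_dataset.X, y, groups=tiny_dataset.groups,
                               config=_tiny_train_config()).fit()


def test_history_records_loss_components_and_validation(tiny_dataset):
    res = LocalGlobalTransformer.from_dataset(tiny_dataset, _tiny_train_config()).fit()
    for col in ("focal", "mcc_penalty", "contrastive", "total", "val_mcc", "val_auc", "lr"):
        assert col in res.history.columns
    assert res.history["total"].notna().all()
    assert "validation" in res.summary() or "MCC" in res.summary()
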
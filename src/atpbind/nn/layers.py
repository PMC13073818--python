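"""Parameterised layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "glorot_uniform",
    "dropout",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform initialisation; fan counts from the two last dims."""
    fan_in = shape[-2] if len(shape) > 1 else shape[-1]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Container with named parameters; supports nested modules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            if v.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = state[k].copy()

    def check_finite(self) -> None:
        for name, p in self.named_parameters().items():
            if not np.all(np.isfinite(p.data)):
                raise FloatingPointError(f"non-finite parameter: {name}")


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        super().__init__()
        self.w = self.add_param("w", glorot_uniform(rng, (in_dim, out_dim)))
        self.b = self.add_param("b", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Self-attention over a (batch, tokens, d_model) sequence."""

    def __init__(self, rng: np.random.Generator, d_model: int, heads: int):
        super().__init__()
        if d_model % heads:
            raise ValueError(f"d_model {d_model} not divisible by heads {heads}")
        self.heads = heads
        self.d_model = d_model
        self.d_head = d_model // heads
        self.wq = self.add_module("wq", Linear(rng, d_model, d_model))
        self.wk = self.add_module("wk", Linear(rng, d_model, d_model))
        self.wv = self.add_module("wv", Linear(rng, d_model, d_model))
        self.wo = self.add_module("wo", Linear(rng, d_model, d_model))

    def __call__(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape

        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, self.heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        # scale q rather than the (tokens x tokens) score matrix: cheaper
        scores = (q * (1.0 / np.sqrt(self.d_head))) @ k.transpose(0, 1, 3, 2)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, self.d_model)
        return self.wo(ctx)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
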
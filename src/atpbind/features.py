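"""Per-residue embedding matrices and their storage.

Classifiers consume :class:`FeatureMatrix` objects and are agnostic to
whether the values came from a protein-language-model adapter, an HDF5
cache, or the synthetic generator. The external adapter (the 1280-wide
``esm2_t33_650M_UR50D`` model) is optional: when it is not importable an
explicit :class:`~atpbind.errors.CapabilityError` is raised, never a silent
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import h5py
import numpy as np

from .errors import CapabilityError, ContractError, IntegrityError
from .io import AMINO_ACIDS, ProteinRecord

__all__ = [
    "FeatureMatrix",
    "EmbeddingAdapter",
    "OneHotAdapter",
    "Esm2Adapter",
    "embed_sequences",
    "save_features",
    "load_features",
    "FeatureStandardizer",
]


@dataclass
class FeatureMatrix:
    """Residues x dim embedding matrix aligned to one chain."""

    chain_id: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ContractError(f"{self.chain_id!r}: feature matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ContractError(f"{self.chain_id!r}: non-finite feature values")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


class EmbeddingAdapter(Protocol):
    """Anything that maps an amino-acid sequence to a residues x dim matrix."""

    dim: int
    name: str

    def embed(self, sequence: str) -> np.ndarray: ...


class OneHotAdapter:
    """Deterministic one-hot encoding of residues, zero-padded to ``dim``.

    A stand-in adapter for tests and examples; it carries no evolutionary
    signal, only residue identity.
    """

    name = "one-hot"

    def __init__(self, dim: int = 64):
        alphabet = AMINO_ACIDS + "X"
        if dim < len(alphabet):
            raise ContractError(f"dim {dim} < alphabet size {len(alphabet)}")
        self.dim = dim
        self._index = {aa: i for i, aa in enumerate(alphabet)}

    def embed(self, sequence: str) -> np.ndarray:
        m = np.zeros((len(sequence), self.dim))
        for row, aa in enumerate(sequence.upper()):
            m[row, self._index.get(aa, self._index["X"])] = 1.0
        return m


class Esm2Adapter:
    """Adapter around the external ESM-2 protein language model.

    Uses the final-layer per-token representations (1280-wide for the
    ``esm2_t33_650M_UR50D`` variant). The model package and weights are
    external; constructing this adapter without them raises a
    :class:`CapabilityError`.
    """

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D"):
        try:
            import esm  # type: ignore
        except ImportError as exc:
            raise CapabilityError(
                f"protein-language-model adapter {model_name!r} requires the 'esm' "
                "package and its weights; use cached features (load_features) or "
                "the synthetic generator instead"
            ) from exc
        self.name = model_name
        self._model, alphabet = getattr(esm.pretrained, model_name)()
        self._model.eval()
        self._batch_converter = alphabet.get_batch_converter()
        self.dim = self._model.embed_dim
        self._layer = self._model.num_layers

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - external
        import torch  # type: ignore

        _, _, tokens = self._batch_converter([("chain", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._layer])
        reps = out["representations"][self._layer][0, 1 : len(sequence) + 1]
        return reps.numpy().astype(np.float64)


def embed_sequences(
    records: Sequence[ProteinRecord], adapter: EmbeddingAdapter
) -> list[FeatureMatrix]:
    """Embed each record's sequence; one matrix per record, rows per residue."""
    out = []
    for rec in records:
        m = adapter.embed(rec.sequence)
        if m.shape != (len(rec), adapter.dim):
            raise ContractError(
                f"adapter returned shape {m.shape} for {rec.chain_id!r}, "
                f"expected {(len(rec), adapter.dim)}"
            )
        out.append(FeatureMatrix(chain_id=rec.chain_id, matrix=m))
    return out


def save_features(matrices: Sequence[FeatureMatrix], path: str | Path) -> None:
    """Save matrices to an HDF5 container with a chain index; lossless."""
    dims = {m.dim for m in matrices}
    if len(dims) > 1:
        raise ContractError(f"inconsistent embedding dims: {sorted(dims)}")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "atpbind-features-v1"
        f.attrs["dim"] = dims.pop() if dims else 0
        index = f.create_group("chains")
        for i, m in enumerate(matrices):
            ds = index.create_dataset(m.chain_id, data=m.matrix)
            ds.attrs["order"] = i


def load_features(path: str | Path, chain_ids: Sequence[str] | None = None) -> list[FeatureMatrix]:
    """Load matrices back, in saved order (or the requested chain order)."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "atpbind-features-v1":
                raise IntegrityError(f"{path}: not an atpbind feature container")
            group = f["chains"]
            if chain_ids is None:
                names = sorted(group, key=lambda k: group[k].attrs["order"])
            else:
                missing = [c for c in chain_ids if c not in group]
                if missing:
                    raise KeyError(f"{path}: chains not in container: {missing}")
                names = list(chain_ids)
            return [FeatureMatrix(chain_id=n, matrix=group[n][()]) for n in names]
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable or corrupt feature container: {exc}") from exc


class FeatureStandardizer:
    """Per-dimension standardisation fitted on training features (default on)."""

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureStandardizer":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ContractError("standardizer not fitted")
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.scale_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
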
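"""Sequence, annotation and prediction file handling.

Protein chains are carried as :class:`ProteinRecord` objects. Residue-level
binding annotations use a three-line-per-chain text dialect: a ``>`` header,
the amino-acid sequence, and a same-length string of ``0``/``1`` labels
(1 = ATP-binding). Predictions are written as a TSV with 1-based residue
indices and three-letter residue identifiers such as ``Gly18``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, ContractError, FormatError

__all__ = [
    "ProteinRecord",
    "DatasetStats",
    "read_fasta",
    "read_annotations",
    "write_annotations",
    "dataset_summary",
    "write_predictions",
    "residue_id",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_LETTERS = set(AMINO_ACIDS) | {"X"}

THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    "X": "Xaa",
}


def residue_id(aa: str, index_1based: int) -> str:
    """Three-letter residue identifier, e.g. ``residue_id('G', 18) == 'Gly18'``."""
    return f"{THREE_LETTER.get(aa.upper(), 'Xaa')}{index_1based}"


@dataclass
class ProteinRecord:
    """One protein chain: identifier, sequence, optional binary binding labels."""

    chain_id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"record {self.chain_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            raise FormatError(
                f"record {self.chain_id!r}: invalid residue letters {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise AlignmentError(
                    f"record {self.chain_id!r}: {len(self.sequence)} residues vs "
                    f"{self.labels.size} labels"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"record {self.chain_id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetStats:
    """Aggregate residue counts over a set of annotated chains."""

    n_chains: int
    n_binding: int
    n_nonbinding: int
    ratio: float = field(init=False)

    def __post_init__(self):
        self.ratio = self.n_nonbinding / self.n_binding if self.n_binding else float("nan")

    def summary(self) -> str:
        return (
            f"chains: {self.n_chains}\n"
            f"binding residues: {self.n_binding}\n"
            f"non-binding residues: {self.n_nonbinding}\n"
            f"non-binding/binding ratio: {self.ratio:.1f}"
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into label-free records, preserving order."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).replace(" ", "").strip()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate chain id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(chain_id=rec.id, sequence=seq))
    return records


def read_annotations(path: str | Path) -> list[ProteinRecord]:
    """Read the three-line header/sequence/labels annotation dialect."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">") or len(header) < 2:
            raise FormatError(f"{path}: expected '>' header at line {i + 1}, got {header!r}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {header!r}")
        chain_id = header[1:].split()[0]
        if chain_id in seen:
            raise FormatError(f"{path}: duplicate chain id {chain_id!r}")
        seen.add(chain_id)
        seq, lab = lines[i + 1], lines[i + 2]
        if set(lab) - {"0", "1"}:
            raise FormatError(
                f"{path}: record {chain_id!r}: label line contains non-binary characters"
            )
        if len(lab) != len(seq):
            raise AlignmentError(
                f"{path}: record {chain_id!r}: sequence length {len(seq)} vs "
                f"label length {len(lab)}"
            )
        records.append(
            ProteinRecord(chain_id=chain_id, sequence=seq, labels=np.frombuffer(lab.encode(), dtype=np.uint8) - ord("0"))
        )
        i += 3
    return records


def write_annotations(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records (with labels) in the three-line annotation dialect."""
    out = []
    for rec in records:
        if rec.labels is None:
            raise ContractError(f"record {rec.chain_id!r} has no labels")
        out.append(f">{rec.chain_id}\n{rec.sequence}\n{''.join(map(str, rec.labels))}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def dataset_summary(records: Sequence[ProteinRecord]) -> DatasetStats:
    """Aggregate binding/non-binding counts and their ratio over all chains."""
    n_binding = 0
    n_total = 0
    for rec in records:
        if rec.labels is None:
            raise ContractError(f"record {rec.chain_id!r} has no labels")
        n_binding += int(rec.labels.sum())
        n_total += len(rec)
    return DatasetStats(
        n_chains=len(records), n_binding=n_binding, n_nonbinding=n_total - n_binding
    )


def write_predictions(
    records: Sequence[ProteinRecord],
    scores: Sequence[np.ndarray],
    threshold: float,
    path: str | Path,
) -> None:
    """Write per-residue probabilities and binary calls as TSV.

    Columns: chain_id, 1-based residue index, amino acid, probability, call.
    A residue is called positive when its score is >= threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ContractError(f"threshold {threshold} outside [0, 1]")
    if len(records) != len(scores):
        raise ContractError(f"{len(records)} records vs {len(scores)} score vectors")
    rows = ["chain_id\tresidue\tamino_acid\tprobability\tcall"]
    for rec, s in zip(records, scores):
        s = np.asarray(s, dtype=float)
        if s.shape != (len(rec),):
            raise ContractError(
                f"record {rec.chain_id!r}: {len(rec)} residues vs {s.size} scores"
            )
        for i, (aa, p) in enumerate(zip(rec.sequence, s), start=1):
            rows.append(f"{rec.chain_id}\t{i}\t{aa}\t{p:.6f}\t{int(p >= threshold)}")
    Path(path).write_text("\n".join(rows) + "\n")
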
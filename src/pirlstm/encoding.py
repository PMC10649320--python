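"""One-hot encoding of RNA sequences and padded batch assembly.

Each base maps to a 4-component indicator vector::

    A -> [1,0,0,0]   U -> [0,1,0,0]   C -> [0,0,1,0]   G -> [0,0,0,1]

``N`` (uncertain base) maps to the all-zero vector.  Batches are padded at
the tail with all-zero rows — deliberately identical to the ``N`` code — and
carry true lengths so downstream consumers can mask the padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import RnaSequence

__all__ = [
    "BASE_TO_VEC",
    "EncodedBatch",
    "encode_base",
    "encode_sequence",
    "decode_sequence",
    "batch_encode",
]

BASE_TO_VEC = {
    "A": (1, 0, 0, 0),
    "U": (0, 1, 0, 0),
    "C": (0, 0, 1, 0),
    "G": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}
_VEC_TO_BASE = {v: k for k, v in BASE_TO_VEC.items()}
_BASE_INDEX = {"A": 0, "U": 1, "C": 2, "G": 3}


@dataclass
class EncodedBatch:
    """Padded stack of one-hot matrices.

    tensor : float array of shape (B, L_max, 4) with {0,1} values
    lengths : int array (B,) of true sequence lengths
    labels : optional int array (B,), 1 = piRNA, 0 = non-piRNA
    """

    tensor: np.ndarray
    lengths: np.ndarray
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return self.tensor.shape[0]


def encode_base(base: str) -> np.ndarray:
    """4-vector code word for a single base."""
    try:
        return np.array(BASE_TO_VEC[base], dtype=np.float64)
    except KeyError:
        raise ValueError(f"not an RNA base: {base!r}") from None


def encode_sequence(seq: RnaSequence | str) -> np.ndarray:
    """L x 4 one-hot matrix for a sequence (rows of N bases are all zero)."""
    bases = seq.bases if isinstance(seq, RnaSequence) else seq
    mat = np.zeros((len(bases), 4), dtype=np.float64)
    for t, b in enumerate(bases):
        if b in _BASE_INDEX:
            mat[t, _BASE_INDEX[b]] = 1.0
        elif b != "N":
            raise ValueError(f"not an RNA base: {b!r} at position {t + 1}")
    return mat


def decode_sequence(enc: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; all-zero rows decode to ``N``."""
    enc = np.asarray(enc)
    if enc.ndim != 2 or enc.shape[1] != 4:
        raise ValueError(f"expected an L x 4 matrix, got shape {enc.shape}")
    out = []
    for t, row in enumerate(enc):
        key = tuple(int(v) for v in row)
        if not np.allclose(row, key):
            raise ValueError(f"row {t} is not a one-hot code word: {row}")
        base = _VEC_TO_BASE.get(key)
        if base is None:
            raise ValueError(f"row {t} is not a one-hot code word: {row}")
        out.append(base)
    return "".join(out)


def batch_encode(seqs: Sequence[RnaSequence | str],
                 labels: Sequence[int] | None = None) -> EncodedBatch:
    """Encode sequences into a tail-padded (B, L_max, 4) tensor with lengths."""
    if len(seqs) == 0:
        raise ValueError("cannot encode an empty batch")
    mats = [encode_sequence(s) for s in seqs]
    lengths = np.array([m.shape[0] for m in mats], dtype=np.int64)
    l_max = int(lengths.max())
    tensor = np.zeros((len(mats), l_max, 4), dtype=np.float64)
    for b, m in enumerate(mats):
        tensor[b, : m.shape[0]] = m
    lab = None if labels is None else np.asarray(labels, dtype=np.int64)
    if lab is not None and lab.shape[0] != len(mats):
        raise ValueError("labels length does not match batch size")
    return EncodedBatch(tensor=tensor, lengths=lengths, labels=lab)
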
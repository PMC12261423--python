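"""Tetranucleotide-frequency (TNF) baseline embedder.

A sequence's TNF is the 256-dimensional vector of sliding-window (stride 1)
4-mer frequencies over the alphabet (A, C, G, T), in lexicographic order.
Windows containing N are skipped; counts are L1-normalized.  No
reverse-complement canonicalization is applied: all 256 4-mers are counted
separately.
"""

from __future__ import annotations

import itertools

import numpy as np

from .records import SequenceRecord

__all__ = ["tnf_embedding", "tnf_embeddings", "KMER_ORDER"]

KMER_ORDER = ["".join(t) for t in itertools.product("ACGT", repeat=4)]
_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _tnf_counts(sequence: str) -> np.ndarray:
    code = np.full(len(sequence), -1, dtype=np.int64)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    for b, i in _BASE.items():
        code[arr == ord(b)] = i
    if len(code) < 4:
        return np.zeros(256)
    win = np.lib.stride_tricks.sliding_window_view(code, 4)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(256)
    idx = win[valid] @ np.array([64, 16, 4, 1])
    return np.bincount(idx, minlength=256).astype(float)


def tnf_embedding(record: SequenceRecord) -> np.ndarray:
    """256-dim 4-mer frequency vector; raises if no N-free window exists."""
    counts = _tnf_counts(record.sequence)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"record {record.seq_id!r} has no 4-mer window free of N"
        )
    return counts / total


def tnf_embeddings(records: list[SequenceRecord]) -> np.ndarray:
    """Stacked TNF vectors, one row per record."""
    return np.stack([tnf_embedding(r) for r in records])
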
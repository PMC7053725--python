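"""Sparse feature-vector utilities shared by both kernels."""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

SparseVector = Mapping[str, float]


def save_kernel_matrix(path: str, K: np.ndarray) -> None:
    """Write a kernel matrix as whitespace-delimited dense text."""
    np.savetxt(path, np.asarray(K, dtype=float), fmt="%.12g")


def load_kernel_matrix(path: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def dot(x: SparseVector, y: SparseVector) -> float:
    """Inner product of two sparse feature vectors."""
    if len(y) < len(x):
        x, y = y, x
    return float(sum(v * y[k] for k, v in x.items() if k in y))


def normdot(x: SparseVector, y: SparseVector) -> float:
    """Cosine-normalized inner product; 0 when either vector is empty/zero."""
    xx, yy = dot(x, x), dot(y, y)
    if xx <= 0.0 or yy <= 0.0:
        return 0.0
    return dot(x, y) / math.sqrt(xx * yy)


def _to_csr(rows: Sequence[SparseVector], vocab: dict[str, int]) -> sp.csr_matrix:
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for row in rows:
        for key, val in row.items():
            idx = vocab.get(key)
            if idx is None:
                idx = vocab[key] = len(vocab)
            indices.append(idx)
            data.append(float(val))
        indptr.append(len(indices))
    return sp.csr_matrix(
        (data, indices, indptr), shape=(len(rows), max(len(vocab), 1))
    )


def block_gram(
    rows_a: Sequence[SparseVector],
    rows_b: Optional[Sequence[SparseVector]] = None,
) -> np.ndarray:
    """Cosine-normalized Gram matrix between two lists of sparse vectors.

    Rows with zero norm (empty patterns) contribute 0 to every entry,
    including their own diagonal.
    """
    vocab: dict[str, int] = {}
    if rows_b is None:
        a = _to_csr(rows_a, vocab)
        b = a
    else:
        # Shared vocabulary; pad column counts to match.
        a = _to_csr(rows_a, vocab)
        b = _to_csr(rows_b, vocab)
        if a.shape[1] < len(vocab):
            a.resize((a.shape[0], len(vocab)))
    gram = np.asarray((a @ b.T).todense(), dtype=float)
    norm_a = np.sqrt(np.asarray(a.multiply(a).sum(axis=1)).ravel())
    norm_b = np.sqrt(np.asarray(b.multiply(b).sum(axis=1)).ravel())
    denom = np.outer(norm_a, norm_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
    return out
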
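"""Gapped k-mer string kernel between RNA windows.

Each length-l word of a sequence contributes one count to each of its
C(l, k) gapped k-mers — the patterns obtained by keeping k informative
positions and wildcarding the other l - k. The kernel between two sequences
is the inner product of their gapped k-mer count vectors; equivalently, by a
counting identity, the sum over all l-mer pairs (u in a, v in b) of
C(l - m(u, v), k), where m is the pair's Hamming distance (zero contribution
when m > l - k). Both routes are implemented: the sparse count-vector route
powers Gram matrices, the Hamming closed form powers single pairs, and tests
pin their exact (integer) agreement.

Sequences are treated as sense-strand RNA; reverse complements are not
merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .exceptions import ConfigError, SequenceTooShortError

_LUT = np.zeros(128, dtype=np.int64)
for _i, _c in enumerate("ACGU"):
    _LUT[ord(_c)] = _i


@dataclass(frozen=True)
class GkmParams:
    """Word length ``l`` and number of informative (non-gap) positions ``k``."""

    l: int = 10
    k: int = 6

    def __post_init__(self):
        if not (1 <= self.k <= self.l):
            raise ConfigError(f"need 1 <= k <= l, got l={self.l}, k={self.k}")
        if self.l > 51:
            raise ConfigError(f"word length l={self.l} exceeds the 51-nt window")

    @property
    def n_masks(self) -> int:
        return comb(self.l, self.k)


@dataclass(frozen=True)
class KernelMatrix:
    """A symmetric positive semidefinite similarity matrix over sequences."""

    values: np.ndarray
    normalized: bool
    ids: tuple[str, ...] | None = None

    def to_tsv(self, path) -> None:
        ids = self.ids or tuple(str(i) for i in range(len(self.values)))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(ids) + "\n")
            for name, row in zip(ids, self.values):
                fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gapped_kmer_count_vector(seq: str, params: GkmParams) -> dict[str, int]:
    """Sparse map from gapped k-mer pattern (wildcard '.') to its count.

    The total count mass is (L - l + 1) * C(l, k): every l-mer contributes
    once per mask.
    """
    l, k = params.l, params.k
    if len(seq) < l:
        raise SequenceTooShortError(
            f"sequence of length {len(seq)} is shorter than l={l}"
        )
    masks = list(combinations(range(l), k))
    counts: dict[str, int] = {}
    for start in range(len(seq) - l + 1):
        word = seq[start : start + l]
        for mask in masks:
            pattern = "".join(word[p] if p in mask else "." for p in range(l))
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def gkm_kernel(a: str, b: str, params: GkmParams) -> float:
    """Closed-form gapped k-mer kernel between two sequences.

    Sums C(l - m, k) over all l-mer pairs with Hamming distance m <= l - k;
    exactly equals the count-vector inner product.
    """
    l, k = params.l, params.k
    for name, s in (("a", a), ("b", b)):
        if len(s) < l:
            raise SequenceTooShortError(
                f"sequence {name} of length {len(s)} is shorter than l={l}"
            )
    wa = sliding_window_view(_encode(a), l)  # (Wa, l)
    wb = sliding_window_view(_encode(b), l)
    mism = (wa[:, None, :] != wb[None, :, :]).sum(axis=2)  # (Wa, Wb)
    contrib = np.array([comb(l - m, k) if m <= l - k else 0 for m in range(l + 1)])
    return float(contrib[mism].sum())


def _count_matrix(seq_arrays: Sequence[np.ndarray], params: GkmParams) -> sparse.csr_matrix:
    """Sparse (n_sequences x n_patterns) gapped k-mer count matrix.

    Patterns are integer-coded per mask (base-4 pack of the informative
    letters, offset by the mask index); codes are compacted with np.unique so
    matrices built in the same call share a column space.
    """
    l, k = params.l, params.k
    masks = list(combinations(range(l), k))
    pow4 = 4 ** np.arange(k, dtype=np.int64)
    rows_all, codes_all = [], []
    for i, arr in enumerate(seq_arrays):
        windows = sliding_window_view(arr, l)  # (W, l)
        per_seq = []
        for m_idx, mask in enumerate(masks):
            codes = windows[:, list(mask)] @ pow4 + m_idx * (4**k)
            per_seq.append(codes)
        codes_i = np.concatenate(per_seq)
        codes_all.append(codes_i)
        rows_all.append(np.full(codes_i.shape, i, dtype=np.int64))
    codes = np.concatenate(codes_all)
    rows = np.concatenate(rows_all)
    _, cols = np.unique(codes, return_inverse=True)
    data = np.ones(len(codes), dtype=np.float64)
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(seq_arrays), int(cols.max()) + 1 if len(cols) else 0)
    )
    return mat


def _check_lengths(seqs: Sequence[str], l: int) -> None:
    for i, s in enumerate(seqs):
        if len(s) < l:
            raise SequenceTooShortError(
                f"sequence at index {i} has length {len(s)} < l={l}"
            )


def gkm_kernel_matrix(
    seqs: Sequence[str],
    params: GkmParams = GkmParams(),
    normalize: bool = True,
    ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Gram matrix of the gapped k-mer kernel over ``seqs``.

    With ``normalize`` each entry is cosine-normalized,
    K'_ij = K_ij / sqrt(K_ii * K_jj), giving unit diagonal.
    """
    _check_lengths(seqs, params.l)
    X = _count_matrix([_encode(s) for s in seqs], params)
    K = np.asarray((X @ X.T).todense(), dtype=float)
    if normalize:
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    return KernelMatrix(
        values=K, normalized=normalize, ids=tuple(ids) if ids is not None else None
    )


def gkm_cross_matrix(
    queries: Sequence[str],
    train: Sequence[str],
    params: GkmParams = GkmParams(),
    normalize: bool = True,
) -> np.ndarray:
    """Rectangular kernel K(queries, train), optionally cosine-normalized."""
    _check_lengths(queries, params.l)
    _check_lengths(train, params.l)
    arrays = [_encode(s) for s in list(queries) + list(train)]
    X = _count_matrix(arrays, params)
    Xq, Xt = X[: len(queries)], X[len(queries) :]
    K = np.asarray((Xq @ Xt.T).todense(), dtype=float)
    if normalize:
        dq = np.sqrt(np.asarray(Xq.multiply(Xq).sum(axis=1)).ravel())
        dt = np.sqrt(np.asarray(Xt.multiply(Xt).sum(axis=1)).ravel())
        K = K / np.outer(dq, dt)
    return K
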
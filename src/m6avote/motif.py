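"""Class-discriminative substring ("motif") features.

From a labeled training fold, every substring with length in
[min_len, max_len] that occurs in sequences of exactly one class becomes a
Boolean presence/absence feature. With ``minimal_only`` a substring is dropped
when one of its proper substrings (within the length bounds) is already kept
on the same side — a superstring's presence implies its substring's presence
on the training data, so the shorter motif carries the information at lower
dimension.

The mined vocabulary is an explicit object passed to the encoder, so encoding
held-out sequences can never silently re-mine on them (anti-leakage by API
shape). Mining uses hashed n-gram sets; the output is defined to equal the
brute-force all-substrings set difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .exceptions import ConfigError

POSITIVE_ONLY = "positive_only"
NEGATIVE_ONLY = "negative_only"


@dataclass(frozen=True)
class MotifEntry:
    substring: str
    side: str  # POSITIVE_ONLY or NEGATIVE_ONLY


@dataclass(frozen=True)
class MotifVocabulary:
    """Ordered, deterministic list of discriminative substrings."""

    entries: tuple[MotifEntry, ...]
    min_len: int = 4
    max_len: int = 12
    minimal_only: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    def substrings(self, side: str | None = None) -> list[str]:
        return [e.substring for e in self.entries if side is None or e.side == side]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("substring\tside\n")
            for e in self.entries:
                fh.write(f"{e.substring}\t{e.side}\n")

    @classmethod
    def from_tsv(cls, path, min_len: int = 4, max_len: int = 12,
                 minimal_only: bool = True) -> "MotifVocabulary":
        entries = []
        with open(path, "r", encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                sub, side = line.split()
                entries.append(MotifEntry(sub, side))
        return cls(tuple(entries), min_len, max_len, minimal_only)


def substring_set(seq: str, min_len: int, max_len: int) -> set[str]:
    """All distinct substrings of ``seq`` with length in [min_len, max_len]."""
    out: set[str] = set()
    L = len(seq)
    for n in range(min_len, min(max_len, L) + 1):
        for i in range(L - n + 1):
            out.add(seq[i : i + n])
    return out


def _minimal_filter(candidates: set[str], min_len: int) -> list[str]:
    """Keep only substrings none of whose proper sub-substrings (length >=
    min_len) are also candidates. Processed in (length, lexicographic) order."""
    kept: set[str] = set()
    order = sorted(candidates, key=lambda s: (len(s), s))
    out = []
    for s in order:
        dominated = False
        for n in range(min_len, len(s)):
            for i in range(len(s) - n + 1):
                if s[i : i + n] in kept:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            kept.add(s)
            out.append(s)
    return out


def mine_from_substring_sets(
    pos_sets: Sequence[set[str]],
    neg_sets: Sequence[set[str]],
    min_len: int = 4,
    max_len: int = 12,
    minimal_only: bool = True,
) -> MotifVocabulary:
    """Mine a vocabulary from precomputed per-sequence substring sets.

    Splitting mining from substring extraction lets cross-validation re-mine
    per fold without re-scanning the sequences.
    """
    if not pos_sets or not neg_sets:
        raise ConfigError("both classes must be non-empty for motif mining")
    if min_len < 1 or max_len < min_len:
        raise ConfigError(
            f"need 1 <= min_len <= max_len, got min_len={min_len}, max_len={max_len}"
        )
    pos_subs: set[str] = set().union(*pos_sets)
    neg_subs: set[str] = set().union(*neg_sets)
    pos_only = pos_subs - neg_subs
    neg_only = neg_subs - pos_subs
    if minimal_only:
        pos_list = _minimal_filter(pos_only, min_len)
        neg_list = _minimal_filter(neg_only, min_len)
    else:
        pos_list, neg_list = sorted(pos_only), sorted(neg_only)
    entries = [MotifEntry(s, POSITIVE_ONLY) for s in pos_list]
    entries += [MotifEntry(s, NEGATIVE_ONLY) for s in neg_list]
    entries.sort(key=lambda e: (len(e.substring), e.substring, e.side))
    return MotifVocabulary(
        entries=tuple(entries),
        min_len=min_len,
        max_len=max_len,
        minimal_only=minimal_only,
    )


def mine_discriminative_substrings(
    positives: Sequence[str],
    negatives: Sequence[str],
    min_len: int = 4,
    max_len: int = 12,
    minimal_only: bool = True,
) -> MotifVocabulary:
    """Mine substrings occurring in exactly one class of the training fold."""
    if min_len < 1 or max_len < min_len:
        raise ConfigError(
            f"need 1 <= min_len <= max_len, got min_len={min_len}, max_len={max_len}"
        )
    return mine_from_substring_sets(
        [substring_set(s, min_len, max_len) for s in positives],
        [substring_set(s, min_len, max_len) for s in negatives],
        min_len=min_len,
        max_len=max_len,
        minimal_only=minimal_only,
    )


def encode_motifs(seq: str, vocab: MotifVocabulary) -> np.ndarray:
    """Boolean presence vector of ``seq`` against the vocabulary entries."""
    subs = substring_set(seq, vocab.min_len, vocab.max_len) if vocab.entries else set()
    return np.fromiter(
        (e.substring in subs for e in vocab.entries), dtype=np.uint8,
        count=len(vocab.entries),
    )


def encode_sets_sparse(
    substring_sets: Sequence[set[str]], vocab: MotifVocabulary
) -> sparse.csr_matrix:
    """Sparse Boolean matrix from precomputed per-sequence substring sets."""
    index = {e.substring: j for j, e in enumerate(vocab.entries)}
    rows, cols = [], []
    for i, subs in enumerate(substring_sets):
        for sub in subs:
            j = index.get(sub)
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(substring_sets), len(vocab.entries))
    )


def encode_motifs_sparse(
    residues: Iterable[str], vocab: MotifVocabulary
) -> sparse.csr_matrix:
    """Sparse Boolean matrix (n_sequences x n_motifs) for the classifier stage."""
    sets = [substring_set(seq, vocab.min_len, vocab.max_len) for seq in residues]
    return encode_sets_sparse(sets, vocab)
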
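"""Text representation: tokens, sparse counts, incremental user state, tf-idf.

The pipeline's first stages: a text is tokenised and mapped to a sparse
vector of term counts over a fixed vocabulary; per-user count vectors are
merged incrementally as new submissions arrive, so the accumulated vector at
any point equals the bag-of-words of everything the user has written so far;
a tf-idf transformation (smoothed idf, L2 normalisation) is applied on read.
The idf statistics are fitted once from an offline training corpus and
frozen for streaming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Vocabulary",
    "CountVector",
    "UserState",
    "TfidfWeights",
    "tokenize",
    "build_vocabulary",
    "vectorize",
    "merge_counts",
    "fit_idf",
    "tfidf_transform",
    "counts_to_csr",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased maximal runs of letters/digits, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Vocabulary:
    """Bijective term -> column index map, indices 0..size-1."""

    index: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def terms(self) -> list[str]:
        ordered = sorted(self.index.items(), key=lambda kv: kv[1])
        return [t for t, _ in ordered]

    def __contains__(self, term: str) -> bool:
        return term in self.index


def build_vocabulary(corpus: Sequence[Sequence[str]], min_df: int = 2) -> Vocabulary:
    """Terms occurring in at least *min_df* documents, indexed lexicographically."""
    if min_df < 1:
        raise ValueError(f"min_df must be >= 1, got {min_df}")
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    df: dict[str, int] = {}
    for tokens in corpus:
        for term in set(tokens):
            df[term] = df.get(term, 0) + 1
    kept = sorted(t for t, n in df.items() if n >= min_df)
    return Vocabulary({t: i for i, t in enumerate(kept)})


@dataclass(frozen=True)
class CountVector:
    """Sparse non-negative term counts over a vocabulary of given size."""

    counts: Mapping[int, int]
    size: int

    def __post_init__(self) -> None:
        for idx, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"stored count must be > 0, got {c} at index {idx}")
            if not (0 <= idx < self.size):
                raise ValueError(f"index {idx} out of range for vocabulary size {self.size}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountVector):
            return NotImplemented
        return self.size == other.size and dict(self.counts) == dict(other.counts)


def vectorize(tokens: Iterable[str], vocab: Vocabulary) -> CountVector:
    """Exact occurrence counts; out-of-vocabulary tokens are ignored."""
    counts: dict[int, int] = {}
    index = vocab.index
    for tok in tokens:
        idx = index.get(tok)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    return CountVector(counts, vocab.size)


@dataclass(frozen=True)
class UserState:
    """Accumulated counts for one user plus the number of merges applied."""

    user: str
    counts: CountVector
    n_submissions: int = 0

    @classmethod
    def empty(cls, user: str, vocab_size: int) -> "UserState":
        return cls(user, CountVector({}, vocab_size), 0)


def merge_counts(state: UserState, cv: CountVector) -> UserState:
    """Fold one submission's counts into the user state (pure; input untouched)."""
    if cv.size != state.counts.size:
        raise ValueError(
            f"vocabulary size mismatch: state {state.counts.size}, vector {cv.size}"
        )
    merged = dict(state.counts.counts)
    for idx, c in cv.counts.items():
        merged[idx] = merged.get(idx, 0) + c
    return UserState(state.user, CountVector(merged, cv.size), state.n_submissions + 1)


@dataclass(frozen=True)
class TfidfWeights:
    """Frozen idf vector (one weight per vocabulary term) + L2 normalisation."""

    idf: np.ndarray
    normalisation: str = "l2"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.idf)):
            raise ValueError("idf weights must be finite")


def fit_idf(corpus: Sequence[CountVector]) -> TfidfWeights:
    """Smoothed inverse document frequency from an offline corpus.

    ``idf_t = ln((1 + N) / (1 + df_t)) + 1`` with N the corpus size; a term
    present in every document gets weight 1, and rarer terms get strictly
    larger weights.
    """
    if len(corpus) == 0:
        raise ValueError("cannot fit idf on an empty corpus")
    size = corpus[0].size
    df = np.zeros(size)
    for cv in corpus:
        if cv.size != size:
            raise ValueError("all corpus vectors must share one vocabulary")
        for idx in cv.counts:
            df[idx] += 1
    n = len(corpus)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    return TfidfWeights(idf=idf)


def counts_to_csr(cv: CountVector) -> sp.csr_matrix:
    """1 x |vocab| CSR row of raw counts."""
    if not cv.counts:
        return sp.csr_matrix((1, cv.size))
    idx = np.fromiter(cv.counts.keys(), dtype=np.int64, count=len(cv.counts))
    val = np.fromiter(cv.counts.values(), dtype=np.float64, count=len(cv.counts))
    order = np.argsort(idx)
    return sp.csr_matrix((val[order], (np.zeros_like(idx), idx[order])), shape=(1, cv.size))


def tfidf_transform(cv: CountVector, weights: TfidfWeights) -> sp.csr_matrix:
    """L2-normalised tf*idf row vector; the zero vector maps to itself."""
    if len(weights.idf) != cv.size:
        raise ValueError(
            f"vocabulary size mismatch: weights {len(weights.idf)}, counts {cv.size}"
        )
    row = counts_to_csr(cv)
    row.data *= weights.idf[row.indices]
    norm = np.sqrt((row.data ** 2).sum())
    if norm > 0:
        row.data /= norm
    return row
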
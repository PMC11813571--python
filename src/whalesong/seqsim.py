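"""Token-level edit distance, the Levenshtein similarity index (LSI) and
set-median strings.

Sequences are compared as whole tokens (phrase-type labels or unit
tokens), not characters: ``"5c"`` and ``"5ce"`` are distinct tokens at
distance 1 by substitution.  The LSI standardizes the minimum number of
insertions, deletions and substitutions by the length of the longer
sequence, yielding a similarity between 0 (disjoint) and 1 (identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, SongCycle, theme_token_sequence

__all__ = [
    "SimilarityMatrix",
    "levenshtein_distance",
    "lsi",
    "similarity_matrix",
    "set_median",
    "median_sequences",
    "lsi_matrix",
]

Token = Hashable
TokenSequence = Sequence[Token]


@dataclass(frozen=True)
class SimilarityMatrix:
    """A labelled symmetric similarity matrix with values in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def levenshtein_distance(a: TokenSequence, b: TokenSequence) -> int:
    """Unit-cost edit distance between two token sequences."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = np.arange(len(b) + 1)
    cur = np.empty(len(b) + 1, dtype=np.int64)
    for i, tok in enumerate(a, start=1):
        cur[0] = i
        sub = prev[:-1] + np.fromiter((tok != t for t in b), count=len(b), dtype=np.int64)
        # rolling minimum over insertion column; cheap explicit loop keeps
        # the recurrence exact
        for j in range(1, len(b) + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub[j - 1])
        prev, cur = cur, prev
    return int(prev[-1])


def lsi(a: TokenSequence, b: TokenSequence) -> float:
    """Levenshtein similarity index: 1 - distance / max(|a|, |b|)."""
    longest = max(len(a), len(b))
    if longest == 0:
        raise ValueError("LSI undefined for two empty sequences")
    return 1.0 - levenshtein_distance(a, b) / longest


def similarity_matrix(sequences: Mapping[str, TokenSequence]) -> SimilarityMatrix:
    """All pairwise LSI values for a labelled set of sequences."""
    labels = tuple(str(k) for k in sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [tuple(sequences[k]) for k in sequences]
    n = len(seqs)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = lsi(seqs[i], seqs[j])
    return SimilarityMatrix(labels, S)


def set_median(sequences: Sequence[TokenSequence], tie: str = "first") -> TokenSequence:
    """The set median: the member minimizing summed edit distance to all
    members of the set (restricted to members; not the generalized median).

    Ties are broken by input order (``tie='first'``, the default, or
    ``'last'`` for sensitivity analysis).
    """
    if not sequences:
        raise ValueError("set median of an empty set is undefined")
    if tie not in ("first", "last"):
        raise ValueError(f"unknown tie rule: {tie!r}")
    sums = [sum(levenshtein_distance(s, t) for t in sequences) for s in sequences]
    best = min(sums)
    idx = [i for i, s in enumerate(sums) if s == best]
    return sequences[idx[0] if tie == "first" else idx[-1]]


def _cycle_tokens(cycle: SongCycle, tokenization: str) -> tuple[str, ...]:
    if tokenization == "phrase_type":
        return cycle.phrase_sequence
    if tokenization == "theme":
        return tuple(theme_token_sequence(cycle))
    raise ValueError(f"unknown tokenization: {tokenization!r}")


def median_sequences(
    corpus: Corpus,
    tokenization: str = "phrase_type",
    tie: str = "first",
    complete_only: bool = True,
) -> dict[str, tuple[str, ...]]:
    """Per-singer median song sequence: the set median over each singer's
    song cycles.

    ``tokenization='phrase_type'`` (default) compares full phrase-type
    sequences as sung; ``'theme'`` collapses to theme tokens keeping
    evolution marks.  Keys are ``singer_id``; incomplete recordings are
    skipped unless ``complete_only=False``.
    """
    recs = corpus.complete_recordings() if complete_only else list(corpus.recordings)
    return {
        r.singer_id: tuple(set_median([_cycle_tokens(c, tokenization) for c in r.cycles], tie=tie))
        for r in recs
    }


def lsi_matrix(
    corpus: Corpus,
    tokenization: str = "phrase_type",
    tie: str = "first",
    complete_only: bool = True,
) -> SimilarityMatrix:
    """LSI matrix over per-singer median sequences."""
    return similarity_matrix(median_sequences(corpus, tokenization, tie, complete_only))
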
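"""Dice's similarity index (DSI) on phrase-type sharing between singers.

DSI ignores the order in which material is sung: each singer is reduced
to the set of phrase types (or theme tokens) appearing anywhere in their
song cycles, and two singers are compared by 2|A∩B| / (|A|+|B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, SingerRecording
from .seqsim import SimilarityMatrix

__all__ = ["ThemeInventory", "inventory", "dice_similarity", "dice_matrix"]


@dataclass(frozen=True)
class ThemeInventory:
    """The set of phrase-type (or theme) tokens a singer sang."""

    singer_id: str
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"singer {self.singer_id}: empty inventory")


def inventory(recording: SingerRecording, level: str = "phrase_type") -> ThemeInventory:
    """Union of tokens over all of a singer's cycles.

    ``level='phrase_type'`` (default) keeps full labels; ``'theme'`` keeps
    theme digits plus evolution marks (variant letters dropped).
    """
    if level == "phrase_type":
        labels = {str(p) for c in recording.cycles for p in c.phrases}
    elif level == "theme":
        labels = {p.theme_token for c in recording.cycles for p in c.phrases}
    else:
        raise ValueError(f"unknown level: {level!r}")
    return ThemeInventory(recording.singer_id, frozenset(labels))


def dice_similarity(a: ThemeInventory, b: ThemeInventory) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two inventories."""
    return 2.0 * len(a.labels & b.labels) / (len(a.labels) + len(b.labels))


def dice_matrix(
    corpus: Corpus, level: str = "phrase_type", complete_only: bool = True
) -> SimilarityMatrix:
    """Pairwise DSI matrix over the corpus' singers.

    Recordings without a complete song cycle are excluded by default.
    """
    recs = corpus.complete_recordings() if complete_only else list(corpus.recordings)
    if len(recs) < 2:
        raise ValueError("need at least 2 recordings")
    invs = [inventory(r, level=level) for r in recs]
    n = len(invs)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = dice_similarity(invs[i], invs[j])
    return SimilarityMatrix(tuple(r.singer_id for r in recs), S)
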
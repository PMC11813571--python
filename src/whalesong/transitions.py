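"""First-order theme-transition structure and stereotypy.

Each song cycle, collapsed to its theme sequence, contributes its
adjacent theme pairs to a per-year transition count matrix; cycle
boundaries are hard breaks and contribute no transition.  Stereotypy is
summarized as the count-weighted mean Shannon entropy of the outgoing
transition distributions — 0 bits when every theme has a single fixed
successor, larger when transitions are variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus, collapse_to_themes

__all__ = ["TransitionMatrix", "transition_counts", "stereotypy"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Observed theme-to-theme transition counts for one year."""

    year: int
    themes: tuple[int, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.themes)
        if c.shape != (n, n):
            raise ValueError("counts shape does not match themes")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.diag(c).any():
            raise ValueError("no self-transitions after theme collapse")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Row-normalized transition proportions (rows without outgoing
        transitions are all zero)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(totals > 0, self.counts / totals, 0.0)
        return P

    def proportion(self, src: int, dst: int) -> float:
        i, j = self.themes.index(src), self.themes.index(dst)
        return float(self.proportions[i, j])

    def observed_once(self) -> list[tuple[int, int]]:
        """Transitions observed exactly once (the dotted lines of a
        transition diagram)."""
        out = []
        for i, a in enumerate(self.themes):
            for j, b in enumerate(self.themes):
                if self.counts[i, j] == 1:
                    out.append((a, b))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.themes), columns=list(self.themes))

    def to_dot(self) -> str:
        """GraphViz DOT export; once-observed transitions are dotted."""
        P = self.proportions
        lines = [f'digraph "transitions_{self.year}" {{']
        for t in self.themes:
            lines.append(f'  "{t}";')
        for i, a in enumerate(self.themes):
            for j, b in enumerate(self.themes):
                if self.counts[i, j] > 0:
                    style = ', style="dotted"' if self.counts[i, j] == 1 else ""
                    lines.append(
                        f'  "{a}" -> "{b}" [label="{100 * P[i, j]:.0f}%"{style}];'
                    )
        lines.append("}")
        return "\n".join(lines)


def transition_counts(corpus: Corpus, year: int, include_incomplete: bool = True) -> TransitionMatrix:
    """Count adjacent theme pairs within each song cycle of a year.

    Incomplete recordings still contribute the transitions they contain
    (their sequences are valid locally) unless excluded.
    """
    recs = [r for r in corpus.recordings if r.year == year]
    if not recs:
        raise ValueError(f"year {year} not present in corpus (has {corpus.years()})")
    if not include_incomplete:
        recs = [r for r in recs if r.complete]
    seqs = [collapse_to_themes(c) for r in recs for c in r.cycles]
    themes = tuple(sorted({t for s in seqs for t in s}))
    idx = {t: i for i, t in enumerate(themes)}
    C = np.zeros((len(themes), len(themes)), dtype=np.int64)
    for s in seqs:
        for a, b in zip(s, s[1:]):
            C[idx[a], idx[b]] += 1
    return TransitionMatrix(year, themes, C)


def stereotypy(matrix: TransitionMatrix) -> float:
    """Count-weighted mean outgoing transition entropy, in bits.

    0 for a fully deterministic song; bounded above by
    log2(n_themes - 1).
    """
    totals = matrix.counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("no transitions observed")
    P = matrix.proportions
    H = 0.0
    for i, n in enumerate(totals):
        if n == 0:
            continue
        p = P[i][P[i] > 0]
        H += n * float(-(p * np.log2(p)).sum())
    return H / totals.sum()
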
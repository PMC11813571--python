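"""Average-linkage (UPGMA) clustering of similarity matrices, cophenetic
correlation, and pvclust-style multiscale bootstrap supports (AU/BP).

Two similarity-to-distance conversions are offered: the elementwise
complement ``d = 1 - s``, and the correlation-profile distance
``d = 1 - r`` where ``r`` is the Pearson correlation between two objects'
columns of the similarity matrix.  The latter is the convention of the R
package pvclust when handed a matrix directly, and is what the packaged
Okinawa reproduction pipeline uses.

UPGMA is implemented here rather than delegated, so that ties in the
merge order are broken deterministically (lexicographically smallest pair
of cluster signatures); scipy's average linkage serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqsim import SimilarityMatrix

__all__ = [
    "Dendrogram",
    "SupportFit",
    "to_distance",
    "upgma",
    "cophenetic_matrix",
    "ccc",
    "bootstrap_support",
    "fit_multiscale",
    "to_newick",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass(frozen=True)
class Dendrogram:
    """A rooted binary merge tree over labelled leaves.

    ``merges`` has one row per internal node: (left child id, right child
    id, height).  Leaves are ids ``0..n-1`` in label order; internal node
    ``k`` has id ``n + k``.  Heights are the average inter-cluster
    distance at the merge and are non-decreasing.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("a binary tree over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of the internal nodes, in merge order."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for k, (a, b, _h) in enumerate(self.merges):
            members[n + k] = members[a] | members[b]
            out.append(members[n + k])
        return out

    def node_heights(self) -> dict[frozenset[str], float]:
        return {clade: h for clade, (_, _, h) in zip(self.clades(), self.merges)}

    def as_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage matrix."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = [a, b, h, sizes[n + k]]
        return Z


def to_distance(S: SimilarityMatrix, method: str = "complement") -> np.ndarray:
    """Convert a similarity matrix to a distance matrix.

    ``'complement'``: d = 1 - s (bounded, zero diagonal).
    ``'correlation'``: d = 1 - Pearson r between the objects' similarity
    profiles (columns of S) — the pvclust default for matrix input.
    """
    if method == "complement":
        D = 1.0 - S.values
    elif method == "correlation":
        D = _correlation_distance(S.values)
    else:
        raise ValueError(f"unknown method: {method!r}")
    np.fill_diagonal(D, 0.0)
    return D


def _correlation_distance(profile: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(profile.T)
    C = np.nan_to_num(C, nan=0.0)
    D = 1.0 - C
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def upgma(D: np.ndarray, labels: tuple[str, ...] | list[str]) -> Dendrogram:
    """Unweighted pair-group average-linkage clustering.

    The pair with the smallest average inter-cluster distance is merged at
    each step; exact ties are broken by the lexicographically smallest
    pair of cluster signatures (sorted leaf-label tuples), making the
    result deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("need a symmetric matrix with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 labels")

    active: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair)
            sig = tuple(sorted((active[i], active[j])))
            key = (d, sig)
            if best is None or key < best[0]:
                best = (key, i, j)
        (_d, _sig), i, j = best
        h = dist[frozenset((i, j))]
        merges.append((i, j, h))
        new_sig = tuple(sorted(active[i] + active[j]))
        si, sj = sizes[i], sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[frozenset((i, j))]
        del active[i], active[j]
        active[next_id] = new_sig
        sizes[next_id] = si + sj
        next_id += 1
    return Dendrogram(tuple(labels), tuple(merges))


def cophenetic_matrix(tree: Dendrogram) -> np.ndarray:
    """Matrix of cophenetic distances (merge height at which two leaves
    first share a cluster)."""
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for k, (a, b, h) in enumerate(tree.merges):
        for x in members[a]:
            for y in members[b]:
                C[x, y] = C[y, x] = h
        members[n + k] = members[a] + members[b]
    return C


def ccc(D: np.ndarray, tree: Dendrogram) -> float:
    """Cophenetic correlation coefficient: Pearson correlation between the
    original distances and the dendrogram's cophenetic distances."""
    n = tree.n_leaves
    if n < 3:
        raise ValueError("CCC undefined for fewer than 3 leaves")
    C = cophenetic_matrix(tree)
    iu = np.triu_indices(n, k=1)
    r, _p = stats.pearsonr(np.asarray(D)[iu], C[iu])
    return float(r)


# ---------------------------------------------------------------------------
# Multiscale bootstrap (AU/BP)


@dataclass(frozen=True)
class SupportFit:
    """Multiscale-bootstrap support for one dendrogram node.

    ``bp_by_scale`` maps each resampling scale r to the proportion of
    replicates in which the node's leaf set reappeared.  ``v`` and ``c``
    are the signed-distance and curvature estimates from the weighted fit
    z(r) = v*sqrt(r) + c/sqrt(r) with z(r) = Phi^-1(1 - BP(r)); the
    approximately unbiased support is AU = 100*(1 - Phi(v - c)).  ``bp``
    is the ordinary bootstrap probability at r = 1, as a percent.
    """

    bp_by_scale: dict[float, float]
    v: float | None
    c: float | None
    au: float | None
    bp: float

    def __post_init__(self) -> None:
        if self.au is not None and not 0 <= self.au <= 100:
            raise ValueError("AU must be in [0, 100]")
        if not 0 <= self.bp <= 100:
            raise ValueError("BP must be in [0, 100]")


def fit_multiscale(bp_by_scale: dict[float, float], B: int) -> SupportFit:
    """Fit the multiscale model to per-scale bootstrap proportions.

    Proportions exactly 0 or 1 get a continuity correction of 0.5/B.
    Weighted least squares with binomial-variance weights; nodes observed
    at fewer than two informative scales get ``au=None``.
    """
    bp_at_1_raw = bp_by_scale.get(1.0, bp_by_scale[min(bp_by_scale, key=lambda r: abs(r - 1.0))])
    # a node present (absent) in every replicate at every scale carries no
    # curvature information; its support is reported at the cap
    if all(bp >= 1.0 for bp in bp_by_scale.values()):
        return SupportFit(dict(bp_by_scale), None, None, 100.0, 100.0 * bp_at_1_raw)
    if all(bp <= 0.0 for bp in bp_by_scale.values()):
        return SupportFit(dict(bp_by_scale), None, None, 0.0, 100.0 * bp_at_1_raw)
    rs, zs, ws = [], [], []
    for r, bp in sorted(bp_by_scale.items()):
        p = min(max(bp, 0.5 / B), 1.0 - 0.5 / B)
        z = stats.norm.ppf(1.0 - p)
        phi = stats.norm.pdf(z)
        var = p * (1.0 - p) / (B * phi**2)
        rs.append(r)
        zs.append(z)
        ws.append(1.0 / var)
    bp_at_1 = bp_by_scale.get(1.0, bp_by_scale[min(bp_by_scale, key=lambda r: abs(r - 1.0))])
    if len(rs) < 2:
        return SupportFit(dict(bp_by_scale), None, None, None, 100.0 * bp_at_1)
    X = np.column_stack([np.sqrt(rs), 1.0 / np.sqrt(rs)])
    sw = np.sqrt(ws)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], np.asarray(zs) * sw, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = 100.0 * float(1.0 - stats.norm.cdf(v - c))
    return SupportFit(dict(bp_by_scale), v, c, min(au, 100.0), 100.0 * bp_at_1)


def bootstrap_support(
    profile: np.ndarray,
    labels: tuple[str, ...] | list[str],
    B: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int | None = None,
    distance: str = "correlation",
) -> tuple[Dendrogram, dict[frozenset[str], SupportFit]]:
    """Multiscale bootstrap of a UPGMA dendrogram, pvclust style.

    ``profile`` is a features-by-objects matrix whose rows are the
    resampling units; for a sequence-derived similarity matrix the
    object-by-object similarity matrix itself is the profile, each
    object's vector of similarities acting as its features.  For each
    scale r, ``ceil(r * n_features)`` rows are resampled with replacement
    B times, the objects are re-clustered, and each observed node's
    reappearance proportion BP(r) is recorded; AU values come from the
    weighted multiscale fit.

    Returns the reference tree (built from the full profile) and a map
    from each internal node's leaf set to its :class:`SupportFit`.
    """
    profile = np.asarray(profile, dtype=float)
    if B < 100:
        raise ValueError("B must be >= 100")
    if min(scales) <= 0:
        raise ValueError("scales must be positive")
    rng = np.random.default_rng(seed)
    n_feat = profile.shape[0]

    def cluster_from(rows: np.ndarray) -> Dendrogram:
        if distance == "correlation":
            D = _correlation_distance(rows)
        elif distance == "euclidean":
            diff = rows[:, :, None] - rows[:, None, :]
            D = np.sqrt((diff**2).sum(axis=0))
        else:
            raise ValueError(f"unknown distance: {distance!r}")
        return upgma(D, labels)

    ref_tree = cluster_from(profile)
    ref_clades = ref_tree.clades()
    counts: dict[float, dict[frozenset[str], int]] = {
        r: {cl: 0 for cl in ref_clades} for r in scales
    }
    for r in scales:
        m = math.ceil(r * n_feat)
        for _ in range(B):
            rows = profile[rng.integers(0, n_feat, size=m)]
            try:
                seen = set(cluster_from(rows).clades())
            except ValueError:  # degenerate resample (e.g. constant rows)
                continue
            for cl in ref_clades:
                if cl in seen:
                    counts[r][cl] += 1
    supports = {
        cl: fit_multiscale({r: counts[r][cl] / B for r in scales}, B) for cl in ref_clades
    }
    return ref_tree, supports


def to_newick(
    tree: Dendrogram, supports: dict[frozenset[str], SupportFit] | None = None
) -> str:
    """Newick serialization with ultrametric branch lengths.

    A node at merge height h places its leaves at depth h/2, so each
    branch length is half the height difference between parent and child.
    AU/BP supports, when given, become internal node labels ``au|bp``.
    """
    n = tree.n_leaves
    half = {i: 0.0 for i in range(n)}
    text = {i: lab for i, lab in enumerate(tree.labels)}
    clades = tree.clades()
    for k, (a, b, h) in enumerate(tree.merges):
        node = n + k
        half[node] = h / 2.0
        parts = []
        for child in (a, b):
            parts.append(f"{text[child]}:{half[node] - half[child]:.6g}")
        label = ""
        if supports is not None and clades[k] in supports:
            s = supports[clades[k]]
            au = "NA" if s.au is None else f"{s.au:.0f}"
            label = f"{au}|{s.bp:.0f}"
        text[node] = f"({parts[0]},{parts[1]}){label}"
    return text[2 * n - 2] + ";"
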
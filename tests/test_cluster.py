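import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from whalesong.cluster import (
    Dendrogram,
    bootstrap_support,
    ccc,
    cophenetic_matrix,
    fit_multiscale,
    to_distance,
    to_newick,
    upgma,
)
from whalesong.seqsim import SimilarityMatrix
from whalesong.synthetic import GeneratorConfig, generate_corpus
from whalesong.seqsim import lsi_matrix


def _random_distance(n, rng):
    D = np.round(rng.uniform(0.05, 1.0, size=(n, n)), 6)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


def _ultrametric(labels, rng):
    """Random ultrametric via a random merge order with increasing heights."""
    clusters = [[lab] for lab in labels]
    n = len(labels)
    C = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.05, 0.3))
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                C[idx[a], idx[b]] = C[idx[b], idx[a]] = h
        clusters[i] = clusters[i] + clusters.pop(j)
    return C


class TestToDistance:
    def test_complement(self):
        S = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.25], [0.25, 1.0]]))
        D = to_distance(S, "complement")
        assert D[0, 1] == pytest.approx(0.75)
        assert D[0, 0] == 0.0

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0.1, 0.9, size=(4, 4))
        S = SimilarityMatrix(tuple("abcd"), np.where(np.eye(4, dtype=bool), 1.0, (M + M.T) / 2))
        for method in ("complement", "correlation"):
            D = to_distance(S, method)
            np.testing.assert_allclose(D, D.T)
            np.testing.assert_allclose(np.diag(D), 0.0)


class TestUpgma:
    def test_two_leaves(self):
        tree = upgma(np.array([[0.0, 0.2], [0.2, 0.0]]), ("A", "B"))
        assert tree.merges == ((0, 1, 0.2),)

    def test_three_leaf_hand_example(self):
        D = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = upgma(D, ("A", "B", "C"))
        assert tree.merges[0] == (0, 1, pytest.approx(0.2))
        # C joins at the average of d(A,C) and d(B,C)
        assert tree.merges[1][2] == pytest.approx(0.7)

    def test_ultrametric_recovered_exactly(self):
        rng = np.random.default_rng(3)
        labels = tuple("abcdefg")
        U = _ultrametric(labels, rng)
        tree = upgma(U, labels)
        np.testing.assert_allclose(cophenetic_matrix(tree), U, atol=1e-12)

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for n in (4, 6, 9):
            D = _random_distance(n, rng)
            labels = tuple(f"L{i}" for i in range(n))
            tree = upgma(D, labels)
            Z = linkage(squareform(D), method="average")
            np.testing.assert_allclose(
                squareform(cophenetic_matrix(tree)), cophenet(Z), atol=1e-9
            )

    def test_agrees_with_naive_recomputation_on_4_leaves(self):
        # oracle: recompute every cluster-pair average from the original
        # matrix at each step instead of using the running update
        rng = np.random.default_rng(11)
        for _ in range(25):
            D = _random_distance(4, rng)
            labels = ("a", "b", "c", "d")
            idx = {lab: i for i, lab in enumerate(labels)}
            clusters = [(lab,) for lab in labels]
            merges = []
            while len(clusters) > 1:
                best = None
                for x, y in itertools.combinations(clusters, 2):
                    avg = np.mean([D[idx[p], idx[q]] for p in x for q in y])
                    if best is None or avg < best[0]:
                        best = (avg, x, y)
                avg, x, y = best
                merges.append((frozenset(x + y), avg))
                clusters.remove(x)
                clusters.remove(y)
                clusters.append(x + y)
            tree = upgma(D, labels)
            got = {clade: h for clade, (_, _, h) in zip(tree.clades(), tree.merges)}
            for clade, h in merges:
                assert got[clade] == pytest.approx(h)

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma(D, ("a", "b"))

    def test_deterministic_tie_break(self):
        # all distances equal: merges proceed in lexicographic label order
        D = np.ones((3, 3)) - np.eye(3)
        tree = upgma(D, ("b", "a", "c"))
        first = tree.clades()[0]
        assert first == frozenset({"a", "b"})


class TestCcc:
    def test_ultrametric_gives_one(self):
        rng = np.random.default_rng(5)
        labels = tuple("abcde")
        U = _ultrametric(labels, rng)
        assert ccc(U, upgma(U, labels)) == pytest.approx(1.0)

    def test_three_leaf_value(self):
        D = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]])
        assert ccc(D, upgma(D, ("A", "B", "C"))) == pytest.approx(0.945, abs=5e-4)

    def test_too_few_leaves(self):
        D = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError):
            ccc(D, upgma(D, ("a", "b")))

    def test_bounded(self):
        rng = np.random.default_rng(9)
        D = _random_distance(7, rng)
        assert -1.0 <= ccc(D, upgma(D, tuple("abcdefg"))) <= 1.0


class TestMultiscaleFit:
    B = 1000
    scales = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))

    def test_flat_half_gives_au_50(self):
        fit = fit_multiscale({r: 0.5 for r in self.scales}, self.B)
        assert fit.v == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)
        assert fit.au == pytest.approx(50.0, abs=1e-6)
        assert fit.bp == pytest.approx(50.0)

    def test_always_present_caps_at_100(self):
        fit = fit_multiscale({r: 1.0 for r in self.scales}, self.B)
        assert fit.bp == 100.0
        assert fit.au >= 99.0

    def test_au_monotone_in_v_minus_c(self):
        # increasing support profiles give decreasing v - c, increasing AU
        fits = [
            fit_multiscale({r: p for r in self.scales}, self.B)
            for p in (0.3, 0.5, 0.7, 0.9)
        ]
        gaps = [f.v - f.c for f in fits]
        aus = [f.au for f in fits]
        assert gaps == sorted(gaps, reverse=True)
        assert aus == sorted(aus)

    def test_single_scale_gives_no_au(self):
        fit = fit_multiscale({1.0: 0.8}, self.B)
        assert fit.au is None
        assert fit.bp == pytest.approx(80.0)


class TestBootstrapSupport:
    def test_two_year_blocks_highly_supported(self):
        cfg = GeneratorConfig(
            years=(2011, 2012),
            year_effect=(1.0, 1.0),
            singers_per_year=4,
            sequence_noise=0.05,
            seed=123,
        )
        corpus, _ = generate_corpus(cfg)
        S = lsi_matrix(corpus)
        tree, supports = bootstrap_support(S.values, S.labels, B=200, seed=0)
        for year in (2011, 2012):
            clade = frozenset(r.singer_id for r in corpus.by_year(year))
            assert clade in supports
            assert supports[clade].au >= 95.0
            assert supports[clade].bp >= 70.0

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(np.eye(3), ("a", "b", "c"), B=10)
        with pytest.raises(ValueError):
            bootstrap_support(np.eye(3), ("a", "b", "c"), B=100, scales=(0.0, 1.0))


class TestNewick:
    def test_two_leaf_branch_lengths_halved(self):
        tree = upgma(np.array([[0.0, 0.2], [0.2, 0.0]]), ("A", "B"))
        assert to_newick(tree) == "(A:0.1,B:0.1);"

    def test_three_leaf_topology(self):
        D = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]])
        nwk = to_newick(upgma(D, ("A", "B", "C")))
        t = dendropy.Tree.get(data=nwk, schema="newick")
        ab = [
            set(leaf.taxon.label for leaf in n.leaf_iter())
            for n in t.preorder_internal_node_iter()
        ]
        assert {"A", "B"} in ab

    def test_round_trip_topology(self):
        rng = np.random.default_rng(21)
        D = _random_distance(6, rng)
        labels = tuple("abcdef")
        tree = upgma(D, labels)
        t = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        parsed = {
            frozenset(leaf.taxon.label for leaf in n.leaf_iter())
            for n in t.preorder_internal_node_iter()
        }
        assert parsed == set(tree.clades()) | {frozenset(labels)}
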
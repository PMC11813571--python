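"""End-to-end reproduction of the Okinawa 2011-2013 analysis.

Runs the packaged transcription fixture through the full pipeline:
per-singer set-median sequences -> LSI matrix -> UPGMA -> cophenetic
correlation; phrase-type inventories -> DSI matrix -> UPGMA -> cophenetic
correlation; the published per-singer complexity scores -> Bartlett
homogeneity check and year-effect regression; and per-year theme
transition matrices with their stereotypy summary.

Clustering uses the correlation-profile distance between the objects'
similarity profiles, matching the convention of the R package pvclust
that the original analysis clustered with; the elementwise complement is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import Dendrogram, SupportFit, bootstrap_support, ccc, to_distance, upgma
from .complexity import BartlettResult, YearModelFit, bartlett_test, year_regression
from .corpus import Corpus
from .dice import dice_matrix
from .okinawa import load_okinawa, load_okinawa_scores
from .seqsim import SimilarityMatrix, lsi_matrix
from .transitions import TransitionMatrix, stereotypy, transition_counts

__all__ = ["OkinawaResults", "okinawa_results"]


@dataclass(frozen=True)
class OkinawaResults:
    corpus: Corpus
    lsi: SimilarityMatrix
    dsi: SimilarityMatrix
    lsi_tree: Dendrogram
    dsi_tree: Dendrogram
    lsi_ccc: float
    dsi_ccc: float
    lsi_supports: dict[frozenset[str], SupportFit] | None
    dsi_supports: dict[frozenset[str], SupportFit] | None
    bartlett: BartlettResult
    regression: YearModelFit
    transitions: dict[int, TransitionMatrix]
    stereotypy: dict[int, float]


def okinawa_results(
    tokenization: str = "phrase_type",
    tie: str = "first",
    distance: str = "correlation",
    bootstrap: int | None = None,
    seed: int | None = None,
) -> OkinawaResults:
    """Run the full Okinawa pipeline and collect every headline statistic.

    ``bootstrap`` (e.g. 1000) adds multiscale AU/BP supports to both
    dendrograms; it is off by default because the point statistics do not
    need it.
    """
    corpus = load_okinawa()
    S_lsi = lsi_matrix(corpus, tokenization=tokenization, tie=tie)
    S_dsi = dice_matrix(corpus)

    trees: dict[str, Dendrogram] = {}
    supports: dict[str, dict | None] = {"lsi": None, "dsi": None}
    for name, S in (("lsi", S_lsi), ("dsi", S_dsi)):
        if bootstrap is not None:
            tree, sup = bootstrap_support(
                S.values, S.labels, B=bootstrap, seed=seed, distance=distance
            )
            supports[name] = sup
        else:
            tree = upgma(to_distance(S, distance), S.labels)
        trees[name] = tree

    scores = load_okinawa_scores()
    groups = {int(y): g["score"].to_numpy() for y, g in scores.groupby("year")}
    bart = bartlett_test(groups)
    fit = year_regression(scores)

    trans = {y: transition_counts(corpus, y) for y in corpus.years()}
    stereo = {y: stereotypy(t) for y, t in trans.items()}

    return OkinawaResults(
        corpus=corpus,
        lsi=S_lsi,
        dsi=S_dsi,
        lsi_tree=trees["lsi"],
        dsi_tree=trees["dsi"],
        lsi_ccc=ccc(to_distance(S_lsi, distance), trees["lsi"]),
        dsi_ccc=ccc(to_distance(S_dsi, distance), trees["dsi"]),
        lsi_supports=supports["lsi"],
        dsi_supports=supports["dsi"],
        bartlett=bart,
        regression=fit,
        transitions=trans,
        stereotypy=stereo,
    )
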
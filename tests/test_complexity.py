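import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from whalesong.complexity import (
    ComplexityVars,
    average_by_singer,
    bartlett_test,
    complexity_scores,
    correlation_report,
    corpus_variables,
    normality_report,
    song_variables,
    transform,
    transform_frame,
    year_regression,
)
from whalesong.corpus import PhraseRecord, SongCycle
from whalesong.labels import parse_label
from whalesong.synthetic import GeneratorConfig, generate_corpus


def _toy_cycle():
    # 10 units, 3 unit types, 2 themes, 60 s span
    labels = [parse_label("1a"), parse_label("2")]
    records = (
        PhraseRecord(labels[0], ("x", "y", "x", "z", "x"), 0.0, 25.0),
        PhraseRecord(labels[1], ("y", "z", "y", "z", "y"), 35.0, 60.0),
    )
    return SongCycle(1, tuple(labels), records)


class TestSongVariables:
    def test_toy_counts(self):
        v = song_variables(_toy_cycle())
        assert (v.n_units, v.n_unit_types, v.duration_s, v.n_themes) == (10, 3, 60.0, 2)

    def test_duplicate_free_units(self):
        lab = parse_label("1a")
        cyc = SongCycle(1, (lab,), (PhraseRecord(lab, ("a", "b", "c"), 0.0, 5.0),))
        v = song_variables(cyc)
        assert v.n_unit_types == v.n_units == 3

    def test_missing_unit_detail_errors(self):
        cyc = SongCycle(1, (parse_label("1a"),))
        with pytest.raises(ValueError, match="unit"):
            song_variables(cyc)

    def test_matches_generator_bookkeeping(self):
        corpus, truth = generate_corpus(GeneratorConfig(seed=5))
        for rec in corpus.recordings:
            for cyc in rec.cycles:
                v = song_variables(cyc)
                n_units, n_types, dur, n_themes = truth.song_variables[
                    (rec.singer_id, cyc.index)
                ]
                assert (v.n_units, v.n_unit_types, v.n_themes) == (
                    n_units, n_types, n_themes,
                )
                assert v.duration_s == pytest.approx(dur)


class TestTransform:
    def test_ln_e_is_one(self):
        e = math.e
        assert transform(ComplexityVars(3, 3, e, 2)) == pytest.approx(
            (math.log(3), math.log(3), 1.0, 4.0)
        )

    def test_unit_point(self):
        assert transform(ComplexityVars(1, 1, 1.0, 1)) == pytest.approx((0, 0, 0, 1))

    def test_monotone(self):
        lo = transform(ComplexityVars(5, 2, 10.0, 2))
        hi = transform(ComplexityVars(9, 4, 30.0, 3))
        assert all(a < b for a, b in zip(lo, hi))

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ComplexityVars(0, 1, 1.0, 1)
        with pytest.raises(ValueError):
            ComplexityVars(2, 3, 1.0, 1)  # more types than units


class TestReports:
    def test_collinear_pairs(self):
        x = np.linspace(1, 5, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": -x})
        rep = correlation_report(df, columns=["a", "b", "c"])
        r = {(row.var_a, row.var_b): row.r for row in rep.itertuples()}
        assert r[("a", "b")] == pytest.approx(1.0)
        assert r[("a", "c")] == pytest.approx(-1.0)

    def test_constant_column_reported_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        rep = correlation_report(df, columns=["a", "b"])
        assert np.isnan(rep["r"].iloc[0])

    def test_independent_normals(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        rep = correlation_report(df, columns=["a", "b"])
        assert abs(rep["r"].iloc[0]) < 0.1
        norm = normality_report(df, columns=["a", "b"])
        assert (norm["W"] > 0.99).all()


class TestPca:
    COLS = ["log_units", "log_unit_types", "log_duration", "themes_sq"]

    def _frame(self, X):
        return pd.DataFrame(X, columns=self.COLS)

    def test_identical_columns_symmetric_loadings(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        res = complexity_scores(self._frame(np.column_stack([x] * 4)))
        np.testing.assert_allclose(res.loadings, 0.5, atol=1e-9)
        assert res.variance_fraction == pytest.approx(1.0)

    def test_sign_convention_on_flip(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 4)) + rng.normal(size=(40, 1))
        a = complexity_scores(self._frame(X))
        b = complexity_scores(self._frame(-X))
        assert a.loadings["log_units"] > 0
        assert b.loadings["log_units"] > 0

    def test_scores_invariant_under_reordering(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        df = self._frame(X)
        perm = rng.permutation(30)
        a = complexity_scores(df)
        b = complexity_scores(df.iloc[perm])
        np.testing.assert_allclose(a.scores.to_numpy()[perm], b.scores.to_numpy(), atol=1e-9)

    def test_loadings_unit_norm_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 4)) + 0.5 * rng.normal(size=(50, 1))
        res = complexity_scores(self._frame(X))
        assert np.sum(res.loadings**2) == pytest.approx(1.0)
        assert res.all_fractions.sum() == pytest.approx(1.0)

    def test_too_few_songs_rejected(self):
        with pytest.raises(ValueError):
            complexity_scores(self._frame(np.zeros((3, 4))))


class TestAveraging:
    def test_mean_per_singer(self):
        df = pd.DataFrame(
            {
                "singer_id": ["a", "a", "b"],
                "year": [2011, 2011, 2011],
                "score": [1.0, -1.0, 2.5],
            }
        )
        out = average_by_singer(df)
        got = dict(zip(out["singer_id"], out["score"]))
        assert got == {"a": 0.0, "b": 2.5}


class TestBartlett:
    def test_equal_variances_give_zero(self):
        res = bartlett_test({1: [0.0, 2.0], 2: [5.0, 7.0]})
        assert res.k2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        res = bartlett_test({1: [0.0, 2.0], 2: [0.0, 4.0]})
        assert res.k2 == pytest.approx(0.2975, abs=5e-4)
        assert res.df == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bartlett_test({1: [1.0, 1.0], 2: [0.0, 2.0]})

    def test_okinawa_scores(self, okinawa_scores):
        groups = {
            int(y): g["score"].to_numpy() for y, g in okinawa_scores.groupby("year")
        }
        res = bartlett_test(groups)
        assert res.k2 == pytest.approx(0.425, abs=5e-4)
        assert res.df == 2


class TestYearRegression:
    def test_identical_group_means_give_zero_f(self):
        df = pd.DataFrame(
            {"year": [2011] * 3 + [2012] * 3, "score": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        )
        fit = year_regression(df)
        assert fit.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_match_pooled_t(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        df = pd.DataFrame(
            {"year": [2011] * 8 + [2012] * 6, "score": np.concatenate([a, b])}
        )
        fit = year_regression(df)
        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert fit.year_t(2012) == pytest.approx(float(t))
        assert fit.year_p(2012) == pytest.approx(float(p))

    def test_singleton_year_flagged(self):
        df = pd.DataFrame({"year": [2011, 2011, 2012], "score": [0.0, 1.0, 2.0]})
        fit = year_regression(df)
        assert fit.singleton_years == (2012,)

    def test_okinawa_scores_reproduce_published_fit(self, okinawa_scores):
        fit = year_regression(okinawa_scores)
        assert fit.adj_r2 == pytest.approx(0.661, abs=5e-4)
        assert fit.f_stat == pytest.approx(15.63, abs=5e-3)
        assert (fit.df_model, fit.df_resid) == (2, 13)
        assert fit.year_t(2012) == pytest.approx(-2.700, abs=5e-4)
        assert fit.year_t(2013) == pytest.approx(3.134, abs=5e-4)


class TestCorpusVariables:
    def test_synthetic_corpus_rows(self):
        corpus, _ = generate_corpus(GeneratorConfig(seed=2))
        df = transform_frame(corpus_variables(corpus))
        assert len(df) == len(corpus) * 2
        assert {"log_units", "log_unit_types", "log_duration", "themes_sq"} <= set(
            df.columns
        )
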
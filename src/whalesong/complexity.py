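"""The four-variable song complexity score and its year-effect analysis.

Per song (one song cycle) four variables are measured: number of units,
number of distinct unit types, duration in seconds, and number of themes.
The count and duration variables are natural-log transformed and the
left-skewed theme count is squared; the first principal component of the
four transformed variables is the *song complexity score*.  Scores are
averaged per singer to avoid over-representing singers with more data,
checked for homogeneity of variance across years (Bartlett), and modelled
by ordinary least squares with the year as a categorical predictor coded
against the earliest year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .corpus import Corpus, SingerRecording, SongCycle, collapse_to_themes

__all__ = [
    "ComplexityVars",
    "TRANSFORMED_COLUMNS",
    "song_variables",
    "corpus_variables",
    "transform",
    "transform_frame",
    "normality_report",
    "correlation_report",
    "PCAResult",
    "complexity_scores",
    "average_by_singer",
    "BartlettResult",
    "bartlett_test",
    "YearModelFit",
    "year_regression",
]

TRANSFORMED_COLUMNS = ["log_units", "log_unit_types", "log_duration", "themes_sq"]


@dataclass(frozen=True)
class ComplexityVars:
    """Raw per-song complexity variables."""

    n_units: int
    n_unit_types: int
    duration_s: float
    n_themes: int

    def __post_init__(self) -> None:
        if min(self.n_units, self.n_unit_types, self.n_themes) <= 0 or self.duration_s <= 0:
            raise ValueError("complexity variables must all be positive")
        if self.n_unit_types > self.n_units:
            raise ValueError("cannot have more unit types than units")


def song_variables(cycle: SongCycle) -> ComplexityVars:
    """Measure the four raw variables for one song cycle.

    Requires unit-level detail (tokens and timing per phrase); duration is
    last unit offset minus first unit onset.
    """
    if cycle.phrase_records is None:
        raise ValueError(
            "cycle has no unit-level detail; complexity needs unit tokens and "
            "times (use a unit-level transcription or the synthetic generator)"
        )
    units = [u for pr in cycle.phrase_records for u in pr.units]
    duration = cycle.phrase_records[-1].offset_s - cycle.phrase_records[0].onset_s
    return ComplexityVars(
        n_units=len(units),
        n_unit_types=len(set(units)),
        duration_s=duration,
        n_themes=len(collapse_to_themes(cycle)),
    )


def corpus_variables(corpus: Corpus, complete_only: bool = True) -> pd.DataFrame:
    """Raw variables for every song in the corpus, one row per
    (singer, cycle)."""
    recs = corpus.complete_recordings() if complete_only else list(corpus.recordings)
    rows = []
    for rec in recs:
        for cyc in rec.cycles:
            v = song_variables(cyc)
            rows.append(
                {
                    "singer_id": rec.singer_id,
                    "year": rec.year,
                    "cycle": cyc.index,
                    "n_units": v.n_units,
                    "n_unit_types": v.n_unit_types,
                    "duration_s": v.duration_s,
                    "n_themes": v.n_themes,
                }
            )
    return pd.DataFrame(rows)


def transform(v: ComplexityVars) -> tuple[float, float, float, float]:
    """(ln units, ln unit types, ln duration, themes²)."""
    return (
        float(np.log(v.n_units)),
        float(np.log(v.n_unit_types)),
        float(np.log(v.duration_s)),
        float(v.n_themes**2),
    )


def transform_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the normalizing transforms to a raw-variable frame."""
    if (df[["n_units", "n_unit_types", "duration_s", "n_themes"]] <= 0).any().any():
        raise ValueError("raw variables must be positive")
    out = df.copy()
    out["log_units"] = np.log(df["n_units"].astype(float))
    out["log_unit_types"] = np.log(df["n_unit_types"].astype(float))
    out["log_duration"] = np.log(df["duration_s"].astype(float))
    out["themes_sq"] = df["n_themes"].astype(float) ** 2
    return out


def normality_report(df: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Shapiro-Wilk W and p per variable (reported, not gating)."""
    columns = columns or TRANSFORMED_COLUMNS
    rows = []
    for col in columns:
        w, p = stats.shapiro(df[col])
        rows.append({"variable": col, "W": float(w), "p": float(p)})
    return pd.DataFrame(rows)


def correlation_report(df: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r and p; constant columns yield NaN."""
    columns = columns or TRANSFORMED_COLUMNS
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"var_a": a, "var_b": b, "r": np.nan, "p": np.nan})
            else:
                r, p = stats.pearsonr(x, y)
                rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAResult:
    """First-principal-component summary of the transformed variables."""

    scores: pd.Series  # PC1 score per song, index matches input frame
    loadings: pd.Series  # PC1 loading per variable
    variance_fraction: float  # share of total variance on PC1
    all_fractions: np.ndarray


def complexity_scores(
    df: pd.DataFrame,
    columns: list[str] | None = None,
    scale: str = "correlation",
) -> PCAResult:
    """PCA of the transformed variables; PC1 is the song complexity score.

    ``scale='correlation'`` (default) standardizes each variable to zero
    mean and unit variance before extracting components;
    ``'covariance'`` only centres them.  The component sign is oriented so
    the loading on the first column (log units) is positive: more units
    means higher complexity.
    """
    columns = columns or TRANSFORMED_COLUMNS
    X = df[columns].to_numpy(float)
    if X.shape[0] < 5:
        raise ValueError("PCA needs at least 5 songs")
    Xc = X - X.mean(axis=0)
    if scale == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant variable; correlation-scale PCA undefined")
        Xc = Xc / sd
    elif scale != "covariance":
        raise ValueError(f"unknown scale: {scale!r}")
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate input: no informative dimension")
    load = vt[0]
    if load[0] < 0:
        load = -load
    scores = Xc @ load
    var = s**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=pd.Series(scores, index=df.index, name="score"),
        loadings=pd.Series(load, index=columns, name="pc1_loading"),
        variance_fraction=float(var[0] / var.sum()),
        all_fractions=var / var.sum(),
    )


def average_by_singer(df: pd.DataFrame) -> pd.DataFrame:
    """Mean complexity score per (singer, year)."""
    return (
        df.groupby(["singer_id", "year"], as_index=False)["score"].mean().sort_values(
            ["year", "singer_id"]
        ).reset_index(drop=True)
    )


@dataclass(frozen=True)
class BartlettResult:
    k2: float
    df: int
    p: float


def bartlett_test(groups: dict[int, "np.ndarray | list[float]"]) -> BartlettResult:
    """Bartlett's test of homogeneity of variance across year groups."""
    if len(groups) < 2:
        raise ValueError("Bartlett test needs at least 2 groups")
    arrays = []
    for year, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {year} has fewer than 2 values")
        if v.var(ddof=1) == 0:
            raise ValueError(f"group {year} has zero variance")
        arrays.append(v)
    k2, p = stats.bartlett(*arrays)
    return BartlettResult(float(k2), len(groups) - 1, float(p))


@dataclass(frozen=True)
class YearModelFit:
    """OLS fit of singer-mean complexity scores on year (categorical,
    reference = earliest year)."""

    reference_year: int
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    f_pvalue: float
    singleton_years: tuple[int, ...]

    def coef_name(self, year: int) -> str:
        return f"C(year, Treatment(reference={self.reference_year}))[T.{year}]"

    def year_t(self, year: int) -> float:
        return float(self.tvalues[self.coef_name(year)])

    def year_coef(self, year: int) -> float:
        return float(self.params[self.coef_name(year)])

    def year_p(self, year: int) -> float:
        return float(self.pvalues[self.coef_name(year)])


def year_regression(df: pd.DataFrame) -> YearModelFit:
    """Fit score ~ year (categorical) by OLS.

    Expects columns ``year`` and ``score`` (one row per singer).  Years
    with a single observation are flagged but the fit proceeds.
    """
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    ref = years[0]
    counts = df.groupby("year").size()
    singletons = tuple(int(y) for y in counts.index[counts == 1])
    model = smf.ols(f"score ~ C(year, Treatment(reference={ref}))", data=df).fit()
    return YearModelFit(
        reference_year=int(ref),
        params=model.params,
        bse=model.bse,
        tvalues=model.tvalues,
        pvalues=model.pvalues,
        adj_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        f_pvalue=float(model.f_pvalue),
        singleton_years=singletons,
    )
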
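# Methods

This note records the models, conventions and numerical choices behind
`whalesong`, in the spirit of a statistical methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Transcription model

A corpus holds one recording per singer per year. Each recording holds
song cycles; a cycle is the transcribed sequence of **phrase types** —
labels of the form *theme digits + optional variant letter (a–d) +
0–2 trailing 'e' marks* (e.g. `2`, `5c`, `1ee`). The variant letter
marks a consistent within-theme variation; each 'e' marks one
between-year **evolution** of the phrase. Transcription convention:
consecutive repeats of one phrase type are written once, while
alternating phrase types of a variable theme (e.g. `5a, 5c, 5a, 5c`) are
written out; collapsing phrase types to their themes and merging
consecutive duplicates therefore yields a cycle's theme sequence with no
immediate repetition.

Two token granularities are used downstream:

- `phrase_type` — the full label (`5ce` ≠ `5c`, distance 1 by
  substitution; evolved phrases are changed material, no partial credit);
- `theme` — theme digits plus the 'e' marks, variant letter dropped
  (`5ce` → `5e`). The 'e' marks are kept because evolution is a
  theme-level event: an evolved theme is a different between-year
  version, and dropping the marks would erase exactly the signal that
  separates consecutive years. Purely numeric themes are used only for
  the transition diagrams, whose nodes are themes irrespective of
  version.

**Eligibility filters.** Recordings can be screened by a minimum unit
signal-to-noise ratio (drop at or below the threshold; a missing SNR
fails the rule only when the rule is enabled, since the packaged corpus
was screened by its authors and carries no SNR values) and by a minimum
within-site time separation (default 24 h; among recordings closer than
that, the earlier is kept) to reduce the chance of sampling one singer
twice. Both filters are idempotent and log dropped ids with reasons into
the corpus provenance.

**Phrase segmentation.** Unit streams are split into phrases at the
largest inter-unit gaps. The threshold is *k* × median inter-unit gap
(default *k* = 3) — a multiplicative rule, because absolute gaps vary
with singer and tempo while the ratio of between-phrase to within-phrase
gaps does not; an absolute threshold in seconds is accepted as an
override. Overlapping units are an error; a single unit is one
single-token phrase.

**The packaged Okinawa corpus.** 17 recordings (6/6/5 across
2011/2012/2013, two sites ~50 km apart), phrase-type sequences per cycle
and the published per-singer average complexity scores (16 singers;
singer 12's recording lacks a complete cycle and is excluded from the
similarity and complexity analyses, though its transitions still count).
The source table's typographic artefacts (`"8 a"`, `"9 a"`, a bare
`"3 "`) are normalized at load time and each normalization is recorded
in the corpus provenance. The bare `3` is read as `3a` — the only
theme-3 variant that singer sings elsewhere in the same recording — and
this override can be disabled.

## Similarity indices

`levenshtein_distance` is the unit-cost edit distance over whole tokens.
`lsi(a, b) = 1 − d(a,b)/max(|a|,|b|)` lies in [0, 1]; it is undefined
for two empty sequences. The per-singer summary sequence is the **set
median** of the singer's cycles — the member minimizing summed distance
to all members (the generalized median string is deliberately not
offered). Ties — which always occur for singers with exactly two cycles
— are broken by input order (`first` by default, `last` available for
sensitivity analysis); the tie rule can move the downstream cophenetic
correlation in the third decimal, which bounds how exactly that statistic
can be pinned down.

`dice_similarity` compares singers' label inventories (union over
cycles, presence/absence, multiplicity ignored): `2|A∩B|/(|A|+|B|)`.
Both a phrase-type-level and a theme-level inventory are available;
phrase-type is the default for the same reason the 'e' marks are kept.

## Clustering and supports

Similarity matrices are converted to distances either elementwise
(`d = 1 − s`) or by the **correlation-profile distance**
(`d = 1 − r` for the Pearson correlation between two objects' columns of
the similarity matrix). The packaged Okinawa pipeline uses the
correlation-profile route, matching the convention of the R package
pvclust when handed a matrix directly — the route under which the
pipeline's cophenetic correlations agree with the published values; the
complement is retained for sensitivity analysis, and the conclusions
that matter (the 2013 clade) hold under both, as the suite asserts.

UPGMA is implemented in-package so that merge ties break
deterministically (lexicographically smallest pair of sorted leaf-label
signatures); scipy's average linkage is the independent cross-check in
the tests, along with a naive oracle that recomputes every cluster-pair
average from the original matrix. Node heights are the average
inter-cluster distance at the merge; cophenetic distance between two
leaves is the height of their first common node, and the CCC is the
Pearson correlation between original and cophenetic distances over the
strict lower triangle. Newick export places leaves of a node at depth
height/2 (branch length = half the height difference), with optional
`AU|BP` internal labels.

**Multiscale bootstrap.** Given a features-by-objects profile (for a
sequence-derived matrix, the similarity matrix itself: each object's
similarity vector is its feature profile — the original R analysis is
ambiguous on this point, so it is an explicit configuration choice), for
each scale r ∈ {0.5, …, 1.4} the rows are resampled with replacement to
size ⌈r·n⌉, B times (default 1000), the objects reclustered, and each
reference node's reappearance proportion BP(r) recorded. With
z(r) = Φ⁻¹(1 − BP(r)), weighted least squares (binomial-variance
weights) fits z(r) = v√r + c/√r; AU = 100·(1 − Φ(v − c)) and BP is
reported at r = 1. Proportions of exactly 0 or 1 at a scale get a
0.5/B continuity correction; a node present (absent) in every replicate
at every scale carries no curvature information and is reported at the
cap, 100 (0); nodes with fewer than two usable scales get no AU rather
than a guess. Because the original resampling target cannot be
recovered exactly, AU/BP values are checked as significance thresholds
(AU > 95, BP > 70) on synthetic block structure, never as exact values.

## Song complexity

Per song (one song cycle with unit-level detail): number of units,
number of distinct unit types, duration (last unit offset − first unit
onset, seconds), number of themes. Natural logs for the first three
(the base is absorbed by standardization), square for the left-skewed
theme count. Shapiro–Wilk and Pearson reports are descriptive, not
gating. PCA is computed on standardized variables by default
(correlation scale): the four transformed variables live on
incommensurable scales (log counts vs squared counts), and
covariance-scale PCA would let the squared theme count dominate; the
covariance option is retained for sensitivity analysis. PC1 is oriented
so the loading on log units is positive (more units ⇒ higher
complexity). Scores are averaged per singer per year; Bartlett's test
(with the small-sample correction factor) checks variance homogeneity;
the year model is OLS with the year indicator-coded against the earliest
year, reporting per-year t and p, the overall F with (k−1, n−k) degrees
of freedom, and adjusted R². The published per-singer scores cannot be
re-derived here because the per-song variable table is unpublished; the
packaged scores are inputs to the regression stage, which the suite
checks against all five published statistics to three decimals.

## Transitions and stereotypy

Cycles are collapsed to numeric theme sequences; adjacent pairs within a
cycle are counted per year (cycle boundaries are hard breaks — no
wrap-around transition, since cycles are delimited precisely to avoid
that ambiguity). Proportions are row-normalized; transitions observed
once are flagged (the dotted lines of a transition diagram; DOT export
available). Stereotypy is the count-weighted mean Shannon entropy of the
outgoing distributions, in bits: 0 for a fully deterministic song,
bounded by log₂(#themes − 1).

## Synthetic corpus generator

The generator emulates the corpus structure the analyses assume, with a
truth record sufficient to recompute every expected quantity. Per year,
a canonical theme order evolves from the previous year: each theme gains
an 'e' with probability ε (cap 2), is deleted with probability μ (at
least two themes always survive), and one new theme is innovated with
probability ν at a random position. Per singer, the canonical order is
perturbed by per-theme dropout δ and adjacent swaps σ. Per cycle, each
theme is sung as a geometric number of phrase repeats, each phrase a
string of units drawn from a per-theme alphabet with log-normal unit
durations and gaps. A per-song size factor
g = year_effect × exp(N(0, σ_song)) scales the expected counts at both
stages (phrase repeats and units per phrase), so the year effect moves
units, duration and unit types together, as in real song where longer
songs carry more of everything.

Defaults are calibrated to the observed study conditions: 3 years × 5
singers × 2 cycles, 6 initial themes, ε = 0.5, ν = 1.0, μ = 0.25 (about
half the themes evolved each year, at least one theme was innovated each
year — theme 7 in 2012, themes 8 and 9 in 2013 — and roughly a third
were lost), σ = 0.05, δ = 0.1 (singers within a year differ by the
occasional omitted theme and swapped position), mean ≈ 9 phrase repeats
per theme and ≈ 4.5 units per phrase (the study transcribed 7507 units
in 1687 phrases over 30 songs), and year effects (1.0, 0.5, 2.0), whose
magnitude is set so that typical fitted year contrasts match the
published ones (|t| ≈ 3) — the printed contrasts are the only observable
calibration for effect size, and the observed cycle lengths (2 to 23
phrases) show a between-year range of this order. All randomness flows
from one seeded generator; identical seeds give byte-identical corpora.

What the generator does **not** emulate: within-theme phrase-type
variants and their alternation runs, acoustic measurement noise,
singer-specific repertoire idiosyncrasies, within-season drift, and
revolution-style wholesale song replacement. Passing recovery tests
therefore show that the pipeline detects year-structured change of the
configured kind at realistic sample sizes — not that it would detect
every pattern present in field recordings.

**Recovery experiments.** (1) *Year-clade purity*: LSI → UPGMA on
generated corpora; for each year, purity = year size / size of the
smallest clade containing all its singers, averaged over years and
seeds. (2) *Year-effect sign recovery*: the full complexity pipeline is
run and the fitted year coefficients' signs are compared with the
configured ones; this arm holds the theme inventory fixed (ν = μ = 0)
because repertoire turnover is itself a genuine complexity change that
would confound the configured count effect. (3) *PC1 variance share*:
the count-based corpus has no closed-form factor structure, so this
check draws the four transformed variables directly from an
equicorrelated one-factor model (pairwise correlation ρ, default 0.6,
near the mean of the published pairwise correlations), for which the
population PC1 share is (1 + 3ρ)/4.

## Problem sizes and determinism

The suite's simulations use 20 seeds for purity, 100 for sign recovery,
2000 songs for the factor-model check, and B = 200 with 10 scales for
bootstrap assertions; these sizes put Monte-Carlo error comfortably
inside the asserted margins while keeping the default run fast.
Property-based tests run derandomized. Edit-distance and set-median
routines are verified exhaustively against an independent
character-level alignment library and a breadth-first edit-script
search on small alphabets.

## Known limitations

- The set-median tie rule and the exact resampling target of the
  original bootstrap are unrecoverable from the published record; both
  are explicit configuration choices, and statistics downstream of them
  (CCC in the third decimal; exact AU/BP values) inherit that
  uncertainty.
- Weighted edit costs, higher-order Markov transition models, and
  mixed-effects complexity models are out of scope.
- The complexity analysis requires unit-level transcriptions; the
  packaged corpus carries phrase-type sequences only, so its complexity
  stage starts from the published per-singer scores.
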
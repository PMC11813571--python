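"""Corpus containers, eligibility filters, phrase segmentation and I/O.

The unit of analysis is a :class:`SingerRecording`: one singer's recording
in one year, holding one or more :class:`SongCycle` objects.  A song cycle
is the sequence of phrase types sung in one pass through the song (themes
never repeat within a cycle, though consecutive phrase types of one theme
may alternate).  Optional unit-level detail (tokens and timing per phrase)
supports the complexity analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .labels import LabelError, PhraseTypeLabel, parse_label

__all__ = [
    "UnitEvent",
    "PhraseRecord",
    "SongCycle",
    "SingerRecording",
    "Corpus",
    "collapse_to_themes",
    "theme_token_sequence",
    "filter_recordings",
    "segment_phrases",
    "read_transcription",
    "write_transcription",
    "read_raven_selection_table",
]


@dataclass(frozen=True)
class UnitEvent:
    """One sung unit: a token with onset/offset in seconds from recording start."""

    token: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"unit {self.token!r}: offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )


@dataclass(frozen=True)
class PhraseRecord:
    """Unit-level detail for one sung phrase instance."""

    label: PhraseTypeLabel
    units: tuple[str, ...]
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("phrase must contain at least one unit")
        if not self.offset_s > self.onset_s:
            raise ValueError("phrase offset must exceed onset")


@dataclass(frozen=True)
class SongCycle:
    """One song cycle: a non-empty sequence of phrase-type labels.

    ``phrases`` is the transcribed sequence in the field's convention:
    consecutive repeats of one phrase type are written once, while
    alternating phrase types of a variable theme are written out.
    ``phrase_records``, when present, hold the unit tokens and timing of
    every sung phrase instance (so it may be longer than ``phrases``).
    """

    index: int
    phrases: tuple[PhraseTypeLabel, ...]
    phrase_records: tuple[PhraseRecord, ...] | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("cycle index must be >= 1")
        if not self.phrases:
            raise ValueError("song cycle must contain at least one phrase")
        if self.phrase_records is not None and not self.phrase_records:
            raise ValueError("phrase_records, when given, must be non-empty")

    @property
    def phrase_sequence(self) -> tuple[str, ...]:
        """Phrase-type tokens in sung order (e.g. ('1a', '2', '3a'))."""
        return tuple(str(p) for p in self.phrases)


@dataclass(frozen=True)
class SingerRecording:
    singer_id: str
    year: int
    site: str
    date: _dt.date
    length_s: float
    cycles: tuple[SongCycle, ...]
    snr_db: float | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError(f"recording {self.singer_id}: length_s must be positive")
        if self.date.year != self.year:
            raise ValueError(
                f"recording {self.singer_id}: date {self.date} outside year {self.year}"
            )
        if not self.cycles:
            raise ValueError(f"recording {self.singer_id}: needs at least one cycle")


@dataclass(frozen=True)
class Corpus:
    """A collection of singer recordings with provenance notes."""

    recordings: tuple[SingerRecording, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        keys = [(r.singer_id, r.year) for r in self.recordings]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (singer_id, year) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.recordings)

    def years(self) -> list[int]:
        return sorted({r.year for r in self.recordings})

    def by_year(self, year: int) -> list[SingerRecording]:
        return [r for r in self.recordings if r.year == year]

    def complete_recordings(self) -> list[SingerRecording]:
        """Recordings with at least one full song cycle transcribed."""
        return [r for r in self.recordings if r.complete]


def collapse_to_themes(cycle: SongCycle) -> list[int]:
    """Theme sequence of a cycle: phrase types mapped to theme numbers,
    consecutive duplicates merged ([9a, 5ce, 5ae, 1ee] -> [9, 5, 1])."""
    out: list[int] = []
    for p in cycle.phrases:
        if not out or out[-1] != p.theme:
            out.append(p.theme)
    return out


def theme_token_sequence(cycle: SongCycle) -> list[str]:
    """Theme-level token sequence keeping evolution marks
    ([9a, 5ce, 5ae, 1ee] -> ['9', '5e', '1ee'])."""
    out: list[str] = []
    for p in cycle.phrases:
        tok = p.theme_token
        if not out or out[-1] != tok:
            out.append(tok)
    return out


def filter_recordings(
    corpus: Corpus,
    min_snr_db: float | None = None,
    min_separation_h: float | None = 24.0,
) -> Corpus:
    """Apply recording-eligibility rules.

    ``min_snr_db`` drops recordings whose unit SNR is at or below the
    threshold (recordings without an SNR measurement fail the rule when it
    is enabled).  ``min_separation_h`` enforces that recordings from the
    same site in the same year be separated in time — among recordings
    closer than the threshold the earlier one is kept, reducing the chance
    of sampling the same singer twice.  Dropped ids and reasons are
    appended to the corpus provenance.  Idempotent.
    """
    notes: list[str] = []
    kept: list[SingerRecording] = []
    for rec in corpus.recordings:
        if min_snr_db is not None and (rec.snr_db is None or rec.snr_db <= min_snr_db):
            notes.append(f"dropped {rec.singer_id} ({rec.year}): snr")
        else:
            kept.append(rec)

    if min_separation_h is not None:
        by_group: dict[tuple[str, int], list[SingerRecording]] = {}
        for rec in kept:
            by_group.setdefault((rec.site, rec.year), []).append(rec)
        kept = []
        for group in by_group.values():
            group.sort(key=lambda r: (r.date, r.singer_id))
            last_kept: _dt.date | None = None
            for rec in group:
                if last_kept is not None:
                    sep_h = (rec.date - last_kept).total_seconds() / 3600.0 if isinstance(
                        rec.date, _dt.datetime
                    ) else (rec.date - last_kept).days * 24.0
                    if sep_h < min_separation_h:
                        notes.append(f"dropped {rec.singer_id} ({rec.year}): separation")
                        continue
                kept.append(rec)
                last_kept = rec.date
        kept.sort(key=lambda r: (r.year, r.date, r.singer_id))

    return Corpus(tuple(kept), corpus.provenance + tuple(notes))


def segment_phrases(
    units: Sequence[UnitEvent],
    k: float = 3.0,
    threshold_s: float | None = None,
) -> list[list[str]]:
    """Segment a time-ordered unit stream into phrases at the largest gaps.

    Phrases are delimited by inter-unit silent gaps exceeding a threshold;
    by default the threshold is ``k`` times the median inter-unit gap
    (scale-free across singers), or an absolute ``threshold_s`` can be
    given.  Returns the unit-token strings of the phrases in order.
    """
    if not units:
        raise ValueError("no units to segment")
    if len(units) == 1:
        return [[units[0].token]]
    gaps = []
    for prev, cur in zip(units, units[1:]):
        gap = cur.onset_s - prev.offset_s
        if gap < 0:
            raise ValueError(
                f"overlapping units at {prev.offset_s:.3f}s/{cur.onset_s:.3f}s"
            )
        gaps.append(gap)
    if threshold_s is None:
        med = sorted(gaps)[len(gaps) // 2] if len(gaps) % 2 else (
            sorted(gaps)[len(gaps) // 2 - 1] + sorted(gaps)[len(gaps) // 2]
        ) / 2.0
        threshold_s = k * med
    phrases: list[list[str]] = [[units[0].token]]
    for gap, unit in zip(gaps, units[1:]):
        if gap > threshold_s:
            phrases.append([unit.token])
        else:
            phrases[-1].append(unit.token)
    return phrases


# ---------------------------------------------------------------------------
# I/O: transcription tables and Raven selection tables

_MANDATORY_COLUMNS = ["singer_id", "year", "site", "date", "cycle", "position", "phrase_type"]
_OPTIONAL_COLUMNS = ["units", "onset_s", "offset_s", "length_s", "snr_db", "complete"]


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "\t" if str(name).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: {path}") from None
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    return df


def read_transcription(path, label_overrides: dict[str, str] | None = None) -> Corpus:
    """Read a transcription table (CSV/TSV) into a :class:`Corpus`.

    One row per sung phrase; mandatory columns ``singer_id, year, site,
    date, cycle, position, phrase_type``; optional columns ``units`` (a
    space-separated unit-token string), ``onset_s``, ``offset_s``,
    ``length_s``, ``snr_db`` and ``complete``.  Labels are normalized
    through the phrase-type grammar, and any normalization that changes
    the text (stray whitespace, explicit overrides) is recorded in the
    corpus provenance.
    """
    df = _read_table(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcription table missing mandatory column(s): {missing}")

    overrides = label_overrides or {}
    notes: list[str] = []
    recordings: list[SingerRecording] = []
    df["year"] = df["year"].astype(int)
    df["cycle"] = df["cycle"].astype(int)
    df["position"] = df["position"].astype(int)

    for (singer, year), g in df.groupby(["singer_id", "year"], sort=False):
        cycles = []
        for cyc_idx, cg in g.groupby("cycle", sort=True):
            cg = cg.sort_values("position")
            labels = []
            records = []
            has_units = "units" in cg.columns and all(u.strip() for u in cg["units"])
            for _, row in cg.iterrows():
                raw = row["phrase_type"]
                text = overrides.get(raw.strip(), raw)
                label = parse_label(text)
                if str(label) != raw:
                    notes.append(
                        f"singer {singer} ({year}) cycle {cyc_idx} pos {row['position']}: "
                        f"normalized {raw!r} -> {str(label)!r}"
                    )
                labels.append(label)
                if has_units:
                    records.append(
                        PhraseRecord(
                            label,
                            tuple(row["units"].split()),
                            float(row["onset_s"]),
                            float(row["offset_s"]),
                        )
                    )
            if has_units:
                # rows are sung phrase instances: transcribe by writing
                # consecutive repeats of a phrase type once
                phrases = [labels[0]]
                for lab in labels[1:]:
                    if lab != phrases[-1]:
                        phrases.append(lab)
            else:
                phrases = labels
            cycles.append(
                SongCycle(int(cyc_idx), tuple(phrases), tuple(records) if records else None)
            )
        first = g.iloc[0]
        recordings.append(
            SingerRecording(
                singer_id=str(singer),
                year=int(year),
                site=first["site"],
                date=_dt.date.fromisoformat(first["date"]),
                length_s=float(first["length_s"]) if "length_s" in g.columns and first["length_s"] else
                max(1.0, sum(len(c.phrases) for c in cycles)),
                cycles=tuple(cycles),
                snr_db=float(first["snr_db"]) if "snr_db" in g.columns and first["snr_db"] else None,
                complete=first.get("complete", "True") not in ("False", "false", "0"),
            )
        )
    return Corpus(tuple(recordings), tuple(notes))


def write_transcription(corpus: Corpus, path) -> None:
    """Write a corpus in the transcription-table format (round-trips
    through :func:`read_transcription`)."""
    rows = []
    for rec in corpus.recordings:
        for cyc in rec.cycles:
            base = {
                "singer_id": rec.singer_id,
                "year": rec.year,
                "site": rec.site,
                "date": rec.date.isoformat(),
                "cycle": cyc.index,
                "length_s": rec.length_s,
                "snr_db": "" if rec.snr_db is None else rec.snr_db,
                "complete": rec.complete,
            }
            if cyc.phrase_records is not None:
                for pos, pr in enumerate(cyc.phrase_records, start=1):
                    rows.append(
                        base
                        | {
                            "position": pos,
                            "phrase_type": str(pr.label),
                            "units": " ".join(pr.units),
                            "onset_s": pr.onset_s,
                            "offset_s": pr.offset_s,
                        }
                    )
            else:
                for pos, phrase in enumerate(cyc.phrases, start=1):
                    rows.append(base | {"position": pos, "phrase_type": str(phrase)})
    pd.DataFrame(rows).to_csv(path, index=False)


_RAVEN_BEGIN = "Begin Time (s)"
_RAVEN_END = "End Time (s)"
_RAVEN_STANDARD = {
    "Selection", "View", "Channel", _RAVEN_BEGIN, _RAVEN_END,
    "Low Freq (Hz)", "High Freq (Hz)", "Delta Time (s)",
}


def read_raven_selection_table(path, annotation_column: str | None = None) -> list[UnitEvent]:
    """Read unit events from a Raven Pro selection table (tab-separated).

    Requires the standard ``Begin Time (s)`` / ``End Time (s)`` columns and
    one annotation column holding the unit token (``Annotation`` by
    default, otherwise the first non-standard column).
    """
    df = _read_table(path, sep="\t")
    for col in (_RAVEN_BEGIN, _RAVEN_END):
        if col not in df.columns:
            raise ValueError(f"Raven selection table missing column: {col!r}")
    if annotation_column is None:
        if "Annotation" in df.columns:
            annotation_column = "Annotation"
        else:
            extras = [c for c in df.columns if c not in _RAVEN_STANDARD]
            if not extras:
                raise ValueError("Raven selection table has no annotation column")
            annotation_column = extras[0]
    elif annotation_column not in df.columns:
        raise ValueError(f"Raven selection table missing column: {annotation_column!r}")
    events = [
        UnitEvent(str(row[annotation_column]), float(row[_RAVEN_BEGIN]), float(row[_RAVEN_END]))
        for _, row in df.iterrows()
    ]
    events.sort(key=lambda e: e.onset_s)
    return events
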
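"""Packaged Okinawa 2011-2013 song transcription fixture.

Seventeen singer recordings from two sites (Kerama Islands and Motobu)
over three boreal-winter breeding seasons, transcribed as phrase-type
sequences per song cycle, plus the published per-singer average song
complexity scores for the sixteen recordings with at least one complete
song cycle (singer 12's recording ends mid-cycle and is excluded from the
similarity and complexity analyses).

The source table contains a few typographic artefacts (stray spaces such
as ``"8 a"``, and one bare ``"3 "`` sung by singer 3, who sings ``3a``
elsewhere in the same recording).  These are normalized at load time and
every normalization is recorded in the corpus provenance; the bare-``3``
override can be disabled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .corpus import Corpus, read_transcription

__all__ = ["load_okinawa", "load_okinawa_scores"]

#: singer 3's bare "3" is read as "3a", the only theme-3 variant that
#: singer sings elsewhere; pass ``normalize_bare_three=False`` to keep "3".
_BARE_THREE_OVERRIDE = {"3": "3a"}


def _data_path(name: str):
    return resources.files("whalesong.data").joinpath(name)


def load_okinawa(normalize_bare_three: bool = True) -> Corpus:
    """Load the packaged Okinawa transcription as a :class:`Corpus`."""
    overrides = _BARE_THREE_OVERRIDE if normalize_bare_three else None
    with resources.as_file(_data_path("okinawa_transcriptions.csv")) as path:
        return read_transcription(path, label_overrides=overrides)


def load_okinawa_scores() -> pd.DataFrame:
    """Published per-singer average song complexity scores.

    Returns a frame with columns ``singer_id`` (str), ``year`` (int) and
    ``score`` (float); 16 rows, one per singer with a complete song cycle.
    """
    with resources.as_file(_data_path("okinawa_complexity.csv")) as path:
        df = pd.read_csv(path, dtype={"singer_id": str})
    df["year"] = df["year"].astype(int)
    return df
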
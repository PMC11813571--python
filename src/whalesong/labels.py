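"""Phrase-type label grammar.

Humpback song transcriptions label every sung phrase with a *phrase type*:
a theme number, an optional variant letter (``a``–``d``) marking a
consistent within-theme variation, and zero, one or two trailing ``e``
marks flagging a between-year *evolved* version of the phrase.  Examples:
``"2"``, ``"1a"``, ``"5ce"``, ``"1ee"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["PhraseTypeLabel", "LabelError", "parse_label", "theme_of"]

_LABEL_RE = re.compile(r"^(\d+)([a-d])?(e{0,2})$")


class LabelError(ValueError):
    """Raised when a phrase-type label cannot be parsed."""


@dataclass(frozen=True, order=True)
class PhraseTypeLabel:
    """A parsed phrase-type label.

    Attributes
    ----------
    theme : int
        Positive theme number.
    variant : str or None
        Optional variant letter ``a``–``d``.
    evolved : int
        Number of trailing ``e`` marks (0, 1 or 2), each denoting one
        between-year evolution of the phrase.
    """

    theme: int
    variant: str | None = None
    evolved: int = 0

    def __post_init__(self) -> None:
        if self.theme < 1:
            raise LabelError(f"theme must be a positive integer, got {self.theme!r}")
        if self.variant is not None and self.variant not in "abcd":
            raise LabelError(f"variant must be one of a-d, got {self.variant!r}")
        if not 0 <= self.evolved <= 2:
            raise LabelError(f"evolved mark count must be 0-2, got {self.evolved!r}")

    def __str__(self) -> str:
        return f"{self.theme}{self.variant or ''}{'e' * self.evolved}"

    @property
    def theme_token(self) -> str:
        """Theme-level token: theme digits plus evolution marks.

        The variant letter is dropped but the ``e`` marks are kept, since
        an evolved theme is a different between-year version of the theme
        (e.g. ``5ce`` -> ``5e``) while variants are within-theme
        alternatives.
        """
        return f"{self.theme}{'e' * self.evolved}"


def parse_label(raw: str) -> PhraseTypeLabel:
    """Parse a textual phrase-type label.

    Whitespace (including internal whitespace such as the typographic
    ``"8 a"``) is removed before parsing.  Raises :class:`LabelError` on
    anything that is not theme digits + optional variant letter +
    up to two ``e`` marks.
    """
    cleaned = re.sub(r"\s+", "", raw)
    if not cleaned:
        raise LabelError(f"empty phrase-type label: {raw!r}")
    m = _LABEL_RE.match(cleaned)
    if m is None:
        raise LabelError(f"malformed phrase-type label: {raw!r}")
    theme, variant, evolved = m.groups()
    return PhraseTypeLabel(int(theme), variant, len(evolved))


def theme_of(label: PhraseTypeLabel | str) -> int:
    """Return the theme number of a label (``"1ee"`` -> 1)."""
    if isinstance(label, str):
        label = parse_label(label)
    return label.theme
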
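"""Shared categorical vocabulary: tone and speaker-group labels."""
from __future__ import annotations

from enum import Enum

from .errors import ValidationError


class Tone(str, Enum):
    """The four tone categories, in canonical report order."""

    RISE = "rise"
    FALL = "fall"
    MID = "mid"
    LOW = "low"

    @classmethod
    def parse(cls, value: "str | Tone") -> "Tone":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown tone symbol: {value!r}") from None


class Group(str, Enum):
    TARGET = "target"
    ENGLISH = "english"
    MANDARIN = "mandarin"

    @classmethod
    def parse(cls, value: "str | Group") -> "Group":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown group label: {value!r}") from None


#: Canonical tone order used for tables and confusion matrices.
TONE_ORDER: tuple[Tone, ...] = (Tone.RISE, Tone.FALL, Tone.MID, Tone.LOW)

#: Level (static) tone categories.
LEVEL_TONES: frozenset[Tone] = frozenset({Tone.MID, Tone.LOW})

#: Chao-numeral labels of the four categories (onset/offset pitch digits).
CHAO_LABEL: dict[Tone, str] = {
    Tone.RISE: "15",
    Tone.FALL: "51",
    Tone.MID: "22",
    Tone.LOW: "11",
}

#: Sentinel for a produced segment string too deviant to align with any target.
NON_TARGET = "NON_TARGET"

#: Sentinel for a tone production that fits none of the four categories.
UNCATEGORIZABLE = "UNCATEGORIZABLE"
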
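"""Categorical scoring of picture-naming productions and tone-error tables.

A production is *correct* only when both the segment string and the tone
category match the target. A *tone-only error* is a segmentally correct
production bearing the wrong tone; the 12 ordered (target, produced) tone
pairs form the error taxonomy. Tone accuracy analyses use only the
segment-correct subset (correct + tone-only errors).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import NON_TARGET, TONE_ORDER, UNCATEGORIZABLE, Group, Tone
from .errors import EmptyInputError, ValidationError

__all__ = [
    "ProductionLabel",
    "OutcomeCategory",
    "NamingOutcome",
    "ErrorTable",
    "ERROR_TYPE_ORDER",
    "score_production",
    "score_ledger",
    "tabulate_errors",
    "summarize_accuracy",
    "read_label_ledger",
    "write_label_ledger",
]

logger = logging.getLogger(__name__)

#: Display order of the 12 tone-only error types: ordered (target, produced)
#: pairs in canonical tone order.
ERROR_TYPE_ORDER: tuple[tuple[Tone, Tone], ...] = tuple(
    (t, p) for t in TONE_ORDER for p in TONE_ORDER if t != p
)


@dataclass(frozen=True)
class ProductionLabel:
    """Authoritative rater labels for one picture-naming production."""

    speaker_id: str
    group: Group
    day: int
    target_segments: str
    target_tone: Tone
    produced_segments: str
    produced_tone: str  # a Tone value or the UNCATEGORIZABLE sentinel
    quality_flag: bool = False
    item: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group.parse(self.group))
        object.__setattr__(self, "target_tone", Tone.parse(self.target_tone))
        if not self.target_segments:
            raise ValidationError("target_segments must be non-empty")
        if not self.produced_segments:
            raise ValidationError(
                f"produced_segments must be non-empty or the {NON_TARGET} marker"
            )
        tone = self.produced_tone
        if isinstance(tone, Tone):
            object.__setattr__(self, "produced_tone", tone.value)
        elif str(tone).strip() != UNCATEGORIZABLE:
            object.__setattr__(self, "produced_tone", Tone.parse(tone).value)
        if self.item is None:
            object.__setattr__(self, "item", f"{self.target_segments}:{self.target_tone.value}")

    @property
    def key(self) -> tuple:
        return (self.speaker_id, self.day, self.item)


class OutcomeCategory(str, Enum):
    CORRECT = "correct"
    TONE_ONLY_ERROR = "tone_only_error"
    SEGMENT_ERROR = "segment_error"
    NON_TARGET = "non_target"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class NamingOutcome:
    key: tuple
    speaker_id: str
    group: Group
    day: int
    target_tone: Tone
    category: OutcomeCategory
    error_type: Optional[tuple[Tone, Tone]] = None  # (target, produced) if tone-only

    def __post_init__(self) -> None:
        if self.category is OutcomeCategory.TONE_ONLY_ERROR:
            if self.error_type is None or self.error_type[0] == self.error_type[1]:
                raise ValidationError("tone-only error requires two distinct tones")
        elif self.error_type is not None:
            raise ValidationError("error_type is only defined for tone-only errors")


def score_production(label: ProductionLabel) -> NamingOutcome:
    """Classify one production into exactly one outcome category."""
    base = dict(
        key=label.key,
        speaker_id=label.speaker_id,
        group=label.group,
        day=label.day,
        target_tone=label.target_tone,
    )
    if label.quality_flag or label.produced_tone == UNCATEGORIZABLE:
        return NamingOutcome(category=OutcomeCategory.EXCLUDED, **base)
    if label.produced_segments == NON_TARGET:
        return NamingOutcome(category=OutcomeCategory.NON_TARGET, **base)
    produced_tone = Tone.parse(label.produced_tone)
    if label.produced_segments == label.target_segments:
        if produced_tone == label.target_tone:
            return NamingOutcome(category=OutcomeCategory.CORRECT, **base)
        return NamingOutcome(
            category=OutcomeCategory.TONE_ONLY_ERROR,
            error_type=(label.target_tone, produced_tone),
            **base,
        )
    return NamingOutcome(category=OutcomeCategory.SEGMENT_ERROR, **base)


def score_ledger(labels: Iterable[ProductionLabel]) -> list[NamingOutcome]:
    return [score_production(lb) for lb in labels]


@dataclass
class ErrorTable:
    """4x4 target-by-produced tone counts per group, zero cells retained.

    Diagonal cells count tone-correct productions among segment-correct
    items; the 12 off-diagonal cells are the tone-only error types.
    """

    tables: dict[tuple, pd.DataFrame]

    @staticmethod
    def _empty() -> pd.DataFrame:
        names = [t.value for t in TONE_ORDER]
        return pd.DataFrame(
            np.zeros((4, 4), dtype=int), index=names, columns=names
        ).rename_axis(index="target_tone", columns="produced_tone")

    def total(self) -> pd.DataFrame:
        out = self._empty()
        for tbl in self.tables.values():
            out += tbl
        return out

    def off_diagonal_count(self, group_key: Optional[tuple] = None) -> int:
        tbl = self.total() if group_key is None else self.tables[group_key]
        arr = tbl.to_numpy()
        return int(arr.sum() - np.trace(arr))

    def marginals(self, group_key: Optional[tuple] = None) -> pd.DataFrame:
        tbl = self.total() if group_key is None else self.tables[group_key]
        out = tbl.copy()
        out["total"] = tbl.sum(axis=1)
        out.loc["total"] = out.sum(axis=0)
        return out


def tabulate_errors(
    outcomes: Sequence[NamingOutcome], by: Sequence[str] = ("group",)
) -> ErrorTable:
    """Count (target tone, produced tone) cells per grouping key.

    Only segment-correct items contribute: correct productions fill the
    diagonal, tone-only errors the off-diagonal cells.
    """
    valid_keys = {"group", "day", "speaker_id"}
    bad = set(by) - valid_keys
    if bad:
        raise ValidationError(f"unknown grouping key(s): {sorted(bad)}")
    tables: dict[tuple, pd.DataFrame] = {}
    for o in outcomes:
        gkey = tuple(getattr(o, k) for k in by)
        if gkey not in tables:
            tables[gkey] = ErrorTable._empty()
        if o.category is OutcomeCategory.CORRECT:
            tables[gkey].loc[o.target_tone.value, o.target_tone.value] += 1
        elif o.category is OutcomeCategory.TONE_ONLY_ERROR:
            tgt, prod = o.error_type
            tables[gkey].loc[tgt.value, prod.value] += 1
    return ErrorTable(tables=tables)


def summarize_accuracy(
    outcomes: Sequence[NamingOutcome],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-speaker and group-level (L1 x day) accuracy summaries.

    Per speaker-day: percent correct of attempted (non-excluded) items and
    the tone-only share of that speaker's errors. Speakers without errors
    contribute no tone-only share (logged). Group rows report mean (sd,
    ddof=1) across speakers.
    """
    if not outcomes:
        raise EmptyInputError("no outcomes to summarize")
    rows = []
    for o in outcomes:
        rows.append(
            {
                "speaker": o.speaker_id,
                "group": o.group.value,
                "day": o.day,
                "category": o.category.value,
            }
        )
    df = pd.DataFrame(rows)
    per_speaker = []
    for (speaker, group, day), sub in df.groupby(["speaker", "group", "day"], sort=True):
        attempted = int((sub["category"] != OutcomeCategory.EXCLUDED.value).sum())
        correct = int((sub["category"] == OutcomeCategory.CORRECT.value).sum())
        tone_only = int((sub["category"] == OutcomeCategory.TONE_ONLY_ERROR.value).sum())
        errors = attempted - correct
        if errors == 0:
            logger.info(
                "speaker %s day %s has zero errors; tone-only share undefined", speaker, day
            )
            share = np.nan
        else:
            share = 100.0 * tone_only / errors
        per_speaker.append(
            {
                "speaker": speaker,
                "group": group,
                "day": day,
                "n_attempted": attempted,
                "pct_correct": 100.0 * correct / attempted if attempted else np.nan,
                "pct_tone_only_of_errors": share,
            }
        )
    speaker_df = pd.DataFrame(per_speaker)
    group_rows = []
    for (group, day), sub in speaker_df.groupby(["group", "day"], sort=True):
        group_rows.append(
            {
                "group": group,
                "day": day,
                "n_speakers": len(sub),
                "pct_correct_mean": float(sub["pct_correct"].mean()),
                "pct_correct_sd": float(sub["pct_correct"].std(ddof=1)),
                "pct_tone_only_mean": float(sub["pct_tone_only_of_errors"].mean()),
                "pct_tone_only_sd": float(sub["pct_tone_only_of_errors"].std(ddof=1)),
            }
        )
    return speaker_df, pd.DataFrame(group_rows)


# ---------------------------------------------------------------------------
# ledger I/O
# ---------------------------------------------------------------------------

_LEDGER_COLUMNS = [
    "speaker",
    "group",
    "day",
    "item",
    "target_segments",
    "target_tone",
    "produced_segments",
    "produced_tone",
    "quality_flag",
]


def read_label_ledger(path: "str | Path") -> list[ProductionLabel]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LEDGER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"label ledger missing column(s): {missing}")
    labels = []
    for _, row in frame.iterrows():
        labels.append(
            ProductionLabel(
                speaker_id=row["speaker"],
                group=Group.parse(row["group"]),
                day=int(row["day"]),
                item=row["item"] or None,
                target_segments=row["target_segments"],
                target_tone=Tone.parse(row["target_tone"]),
                produced_segments=row["produced_segments"],
                produced_tone=row["produced_tone"],
                quality_flag=str(row["quality_flag"]).strip().lower() in {"1", "true", "yes"},
            )
        )
    return labels


def write_label_ledger(labels: Iterable[ProductionLabel], path: "str | Path") -> None:
    rows = [
        {
            "speaker": lb.speaker_id,
            "group": lb.group.value,
            "day": lb.day,
            "item": lb.item,
            "target_segments": lb.target_segments,
            "target_tone": lb.target_tone.value,
            "produced_segments": lb.produced_segments,
            "produced_tone": lb.produced_tone,
            "quality_flag": int(lb.quality_flag),
        }
        for lb in labels
    ]
    pd.DataFrame(rows, columns=_LEDGER_COLUMNS).to_csv(path, sep="\t", index=False)
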
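"""Ingestion, validation, repair and truncation of sampled F0 trajectories.

Supports two on-disk sources: time-normalized tab-separated tables (one row
per production, a fixed number of equidistant F0 samples in Hz plus
metadata) and Praat PitchTier text files in the "short" and "long" dialects.
Bookkeeping of planned vs. retained trials is carried by
:class:`ExclusionLedger`.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Group, Tone
from .errors import (
    DialectError,
    EmptyInputError,
    FormatError,
    IrreparableContourError,
    ValidationError,
)

__all__ = [
    "F0Trajectory",
    "SpeakerRange",
    "ExclusionReason",
    "ExclusionLedger",
    "TableDialect",
    "PitchTier",
    "RepairResult",
    "read_normtime_table",
    "write_normtime_table",
    "read_pitchtier",
    "resample_pitchtier",
    "repair_contour",
    "truncate_edges",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class F0Trajectory:
    """One production's sampled pitch track in Hz with its metadata.

    ``samples`` may contain ``None`` entries (missing/unmeasurable F0)
    before repair; all non-null samples must be positive.
    """

    speaker_id: str
    group: Group
    item: str
    tone: Tone
    day: int
    samples: tuple[Optional[float], ...]
    duration_ms: float
    rep: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group.parse(self.group))
        object.__setattr__(self, "tone", Tone.parse(self.tone))
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.duration_ms <= 0:
            raise ValidationError(f"duration_ms must be > 0, got {self.duration_ms}")
        for i, s in enumerate(self.samples):
            if s is not None and (not math.isfinite(s) or s <= 0):
                raise ValidationError(f"sample {i} must be a positive finite Hz value, got {s}")

    @property
    def key(self) -> tuple:
        return (self.speaker_id, self.day, self.item, self.rep)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_missing(self) -> int:
        return sum(s is None for s in self.samples)

    def values(self) -> np.ndarray:
        """Samples as a float array with NaN in place of missing entries."""
        return np.array([np.nan if s is None else s for s in self.samples], dtype=float)


@dataclass(frozen=True)
class SpeakerRange:
    """A speaker's pitch range (xmin, xmax) in Hz."""

    speaker_id: str
    xmin: float
    xmax: float

    def __post_init__(self) -> None:
        if not (0 < self.xmin < self.xmax):
            raise ValidationError(
                f"speaker range must satisfy 0 < xmin < xmax, got ({self.xmin}, {self.xmax})"
            )


class ExclusionReason(str, Enum):
    RECORDING_ERROR = "recording_error"
    NON_RESPONSE = "non_response"
    UNCATEGORIZABLE_TONE = "uncategorizable_tone"
    BAD_QUALITY = "bad_quality"


@dataclass
class ExclusionLedger:
    """Planned-design bookkeeping: planned = retained + excluded, always."""

    planned: list[tuple] = field(default_factory=list)
    exclusions: list[tuple[tuple, ExclusionReason]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._planned_set = set(self.planned)
        self._excluded_set = {k for k, _ in self.exclusions}

    def exclude(self, key: tuple, reason: "ExclusionReason | str") -> None:
        reason = ExclusionReason(reason)
        if key not in self._planned_set:
            raise ValidationError(f"excluded key {key!r} is not in the planned design")
        if key in self._excluded_set:
            raise ValidationError(f"key {key!r} already excluded")
        self.exclusions.append((key, reason))
        self._excluded_set.add(key)

    @property
    def planned_count(self) -> int:
        return len(self.planned)

    @property
    def excluded_count(self) -> int:
        return len(self.exclusions)

    @property
    def retained_count(self) -> int:
        return self.planned_count - self.excluded_count

    def retained_keys(self) -> list[tuple]:
        return [k for k in self.planned if k not in self._excluded_set]

    def is_excluded(self, key: tuple) -> bool:
        return key in self._excluded_set

    def check(self) -> None:
        """Assert the conservation invariant; raises on violation."""
        if self.retained_count != self.planned_count - self.excluded_count:
            raise ValidationError("ledger conservation violated")
        for k in self._excluded_set:
            if k not in self._planned_set:
                raise ValidationError(f"excluded key {k!r} not planned")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"key": "/".join(map(str, k)), "reason": r.value} for k, r in self.exclusions]
        return pd.DataFrame(rows, columns=["key", "reason"])

    def write_tsv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normtime tables
# ---------------------------------------------------------------------------

#: Cell contents treated as a missing F0 measurement.
MISSING_TOKENS = frozenset({"", "--undefined--", "NA", "NaN", "nan", "na"})


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a time-normalized F0 table."""

    speaker: str = "speaker"
    group: str = "group"
    item: str = "item"
    tone: str = "tone"
    day: str = "day"
    duration: str = "duration_ms"
    rep: str = "rep"
    sample_columns: tuple[str, ...] = tuple(f"f{i:02d}" for i in range(1, 21))
    exclude_reason: str = "exclude_reason"
    n_samples: int = 20

    def __post_init__(self) -> None:
        if len(self.sample_columns) != self.n_samples:
            raise DialectError(
                f"dialect declares {self.n_samples} samples but maps "
                f"{len(self.sample_columns)} sample columns"
            )


DEFAULT_DIALECT = TableDialect()


def _parse_f0_cell(cell: str) -> Optional[float]:
    token = str(cell).strip()
    if token in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        return None
    if not math.isfinite(value) or value <= 0:
        return None
    return value


def read_normtime_table(
    path: "str | Path", dialect: TableDialect = DEFAULT_DIALECT
) -> tuple[list[F0Trajectory], ExclusionLedger]:
    """Read a time-normalized F0 table into trajectories plus a ledger.

    Every row enters the planned design. Rows carrying a non-empty exclusion
    reason (optional ``exclude_reason`` column) are routed to the ledger and
    produce no trajectory; unparseable F0 cells become null samples on the
    trajectory, to be handled by :func:`repair_contour`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    mandatory = [dialect.speaker, dialect.group, dialect.item, dialect.tone,
                 dialect.day, dialect.duration]
    for col in mandatory:
        if col not in frame.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path.name}")
    missing_samples = [c for c in dialect.sample_columns if c not in frame.columns]
    if missing_samples:
        raise DialectError(
            f"{len(missing_samples)} of {dialect.n_samples} sample columns missing "
            f"(first: {missing_samples[0]!r})"
        )

    has_rep = dialect.rep in frame.columns
    has_reason = dialect.exclude_reason in frame.columns

    trajectories: list[F0Trajectory] = []
    planned: list[tuple] = []
    excluded: list[tuple[tuple, str]] = []
    for _, row in frame.iterrows():
        rep = int(row[dialect.rep]) if has_rep else 1
        key = (row[dialect.speaker], int(row[dialect.day]), row[dialect.item], rep)
        planned.append(key)
        reason = str(row[dialect.exclude_reason]).strip() if has_reason else ""
        if reason:
            excluded.append((key, reason))
            continue
        samples = tuple(_parse_f0_cell(row[c]) for c in dialect.sample_columns)
        trajectories.append(
            F0Trajectory(
                speaker_id=row[dialect.speaker],
                group=Group.parse(row[dialect.group]),
                item=row[dialect.item],
                tone=Tone.parse(row[dialect.tone]),
                day=int(row[dialect.day]),
                samples=samples,
                duration_ms=float(row[dialect.duration]),
                rep=rep,
            )
        )
    ledger = ExclusionLedger(planned=planned)
    for key, reason in excluded:
        ledger.exclude(key, reason)
    ledger.check()
    return trajectories, ledger


def write_normtime_table(
    trajectories: Iterable[F0Trajectory],
    path: "str | Path",
    dialect: TableDialect = DEFAULT_DIALECT,
    missing_token: str = "--undefined--",
) -> None:
    """Write trajectories in the tab-separated layout `read_normtime_table` reads."""
    rows = []
    for t in trajectories:
        if t.n_samples != dialect.n_samples:
            raise DialectError(
                f"trajectory {t.key} has {t.n_samples} samples; dialect expects {dialect.n_samples}"
            )
        row = {
            dialect.speaker: t.speaker_id,
            dialect.group: t.group.value,
            dialect.item: t.item,
            dialect.tone: t.tone.value,
            dialect.day: t.day,
            dialect.rep: t.rep,
            dialect.duration: repr(t.duration_ms),
        }
        for col, s in zip(dialect.sample_columns, t.samples):
            row[col] = missing_token if s is None else repr(float(s))
        rows.append(row)
    columns = [dialect.speaker, dialect.group, dialect.item, dialect.tone,
               dialect.day, dialect.rep, dialect.duration, *dialect.sample_columns]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Praat PitchTier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PitchTier:
    """(time, Hz) anchor points of a Praat PitchTier, ascending in time."""

    xmin: float
    xmax: float
    times: tuple[float, ...]
    values: tuple[float, ...]

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def voiced_span_ms(self) -> float:
        if self.n_points < 2:
            return 0.0
        return 1000.0 * (self.times[-1] - self.times[0])


_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def read_pitchtier(path: "str | Path") -> PitchTier:
    """Parse a Praat PitchTier text file (short or long dialect)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    header = "\n".join(lines[:2])
    if "ooTextFile" not in header or "PitchTier" not in header:
        raise FormatError(f"{path.name} is not a Praat PitchTier text file")
    body = [ln.strip() for ln in lines[2:] if ln.strip()]
    if any("=" in ln for ln in body):
        return _parse_long_pitchtier(body, path.name)
    return _parse_short_pitchtier(body, path.name)


def _parse_short_pitchtier(body: list[str], name: str) -> PitchTier:
    numbers: list[float] = []
    for ln in body:
        m = _NUM_RE.fullmatch(ln)
        if m is None:
            raise FormatError(f"unexpected line in short PitchTier {name}: {ln!r}")
        numbers.append(float(ln))
    if len(numbers) < 3:
        raise FormatError(f"truncated short PitchTier {name}")
    xmin, xmax, n = numbers[0], numbers[1], int(numbers[2])
    if n == 0:
        raise EmptyInputError(f"PitchTier {name} contains zero points")
    pairs = numbers[3:]
    if len(pairs) != 2 * n:
        raise FormatError(f"short PitchTier {name}: expected {2 * n} numbers, found {len(pairs)}")
    times = tuple(pairs[0::2])
    values = tuple(pairs[1::2])
    return _finish_pitchtier(xmin, xmax, times, values, name)


def _parse_long_pitchtier(body: list[str], name: str) -> PitchTier:
    def _grab(pattern: str, ln: str) -> Optional[float]:
        m = re.match(pattern, ln)
        return float(m.group(1)) if m else None

    xmin = xmax = None
    n = None
    times: list[float] = []
    values: list[float] = []
    for ln in body:
        if (v := _grab(r"xmin\s*=\s*(\S+)", ln)) is not None:
            xmin = v
        elif (v := _grab(r"xmax\s*=\s*(\S+)", ln)) is not None:
            xmax = v
        elif (v := _grab(r"points:\s*size\s*=\s*(\S+)", ln)) is not None:
            n = int(v)
        elif (v := _grab(r"(?:number|time)\s*=\s*(\S+)", ln)) is not None:
            times.append(v)
        elif (v := _grab(r"value\s*=\s*(\S+)", ln)) is not None:
            values.append(v)
    if xmin is None or xmax is None or n is None:
        raise FormatError(f"long PitchTier {name}: missing xmin/xmax/size header fields")
    if n == 0:
        raise EmptyInputError(f"PitchTier {name} contains zero points")
    if len(times) != n or len(values) != n:
        raise FormatError(f"long PitchTier {name}: declared {n} points, found {len(times)}")
    return _finish_pitchtier(xmin, xmax, tuple(times), tuple(values), name)


def _finish_pitchtier(xmin, xmax, times, values, name) -> PitchTier:
    order = np.argsort(times, kind="stable")
    times = tuple(float(times[i]) for i in order)
    values = tuple(float(values[i]) for i in order)
    if any(v <= 0 for v in values):
        raise FormatError(f"PitchTier {name}: non-positive F0 value")
    return PitchTier(xmin=float(xmin), xmax=float(xmax), times=times, values=values)


def resample_pitchtier(tier: PitchTier, n_points: int = 20) -> np.ndarray:
    """Resample to ``n_points`` equidistant samples over the voiced span.

    Linear interpolation between anchors; endpoints are preserved exactly.
    """
    if tier.n_points == 0:
        raise EmptyInputError("cannot resample an empty PitchTier")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    grid = np.linspace(tier.times[0], tier.times[-1], n_points)
    return np.interp(grid, np.array(tier.times), np.array(tier.values))


# ---------------------------------------------------------------------------
# repair and truncation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepairResult:
    trajectory: F0Trajectory
    repaired: tuple[int, ...]  # 0-based positions that were filled or replaced

    @property
    def n_repaired(self) -> int:
        return len(self.repaired)


def _ratio(a: float, b: float) -> float:
    r = a / b
    return max(r, 1.0 / r)


def _flag_excursions(x: np.ndarray, jump_ratio: float) -> list[int]:
    """Indices of isolated octave-jump-like spikes among valid samples.

    A valid sample is flagged when it deviates from both flanking valid
    neighbours by more than ``jump_ratio`` while those neighbours agree with
    each other (so steep but consistent movements are never touched). At the
    contour edges the rule degenerates to the single available neighbour,
    guarded by agreement of the two samples beyond it.
    """
    valid = np.flatnonzero(~np.isnan(x))
    flags: list[int] = []
    v = x[valid]
    m = len(valid)
    for j in range(m):
        if 0 < j < m - 1:
            if (
                _ratio(v[j], v[j - 1]) > jump_ratio
                and _ratio(v[j], v[j + 1]) > jump_ratio
                and _ratio(v[j - 1], v[j + 1]) <= jump_ratio
            ):
                flags.append(int(valid[j]))
        elif j == 0 and m >= 3:
            if _ratio(v[0], v[1]) > jump_ratio and _ratio(v[1], v[2]) <= jump_ratio:
                flags.append(int(valid[0]))
        elif j == m - 1 and m >= 3:
            if _ratio(v[-1], v[-2]) > jump_ratio and _ratio(v[-2], v[-3]) <= jump_ratio:
                flags.append(int(valid[-1]))
    return flags


def repair_contour(traj: F0Trajectory, jump_ratio: float = 1.8) -> RepairResult:
    """Fill missing samples and isolated pitch excursions by interpolation.

    Interpolation is linear in log-F0 between the nearest valid neighbours;
    leading/trailing gaps are filled with the nearest valid value. Raises
    :class:`IrreparableContourError` when fewer than two valid samples
    remain, in which case the trial should be routed to the exclusion
    ledger by the caller.
    """
    if jump_ratio <= 1.0:
        raise ValidationError(f"jump_ratio must exceed 1, got {jump_ratio}")
    x = traj.values()
    repaired_positions: set[int] = set(np.flatnonzero(np.isnan(x)).tolist())
    # iterate to a fixed point: filling a gap can expose a new edge excursion
    for _ in range(len(x)):
        flagged = _flag_excursions(x, jump_ratio)
        x[flagged] = np.nan
        repaired_positions.update(flagged)
        invalid = np.isnan(x)
        if (~invalid).sum() < 2:
            raise IrreparableContourError(
                f"trial {traj.key}: fewer than 2 valid samples after excursion flagging"
            )
        if invalid.any():
            valid_idx = np.flatnonzero(~invalid)
            first, last = int(valid_idx[0]), int(valid_idx[-1])
            # leading/trailing gaps copy the nearest valid value exactly
            x[:first] = x[first]
            x[last + 1:] = x[last]
            interior = np.flatnonzero(np.isnan(x))
            if interior.size:
                x[interior] = np.exp(
                    np.interp(interior, valid_idx, np.log(x[valid_idx]))
                )
        if not flagged and not invalid.any():
            break
    fixed = replace(traj, samples=tuple(float(v) for v in x))
    return RepairResult(trajectory=fixed, repaired=tuple(sorted(repaired_positions)))


def truncate_edges(traj: F0Trajectory, n_drop: int = 2) -> F0Trajectory:
    """Drop the first and last ``n_drop`` samples, keeping all metadata."""
    if n_drop < 0:
        raise ValidationError(f"n_drop must be non-negative, got {n_drop}")
    if n_drop == 0:
        return traj
    if traj.n_samples <= 2 * n_drop:
        raise ValidationError(
            f"cannot drop {n_drop} samples from each edge of a "
            f"{traj.n_samples}-sample trajectory"
        )
    return replace(traj, samples=traj.samples[n_drop:-n_drop])
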
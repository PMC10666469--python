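"""T-value normalization, DCT shape features, tonal centroids and distances.

The pitch normalization maps a speaker's log-F0 range onto the 0-5 scale:

    T(x) = 5 * (log10 x - log10 xmin) / (log10 xmax - log10 xmin)

Shape features are the first three coefficients of a type-II DCT,

    c_k = sum_{n=0..N-1} x_n * cos(pi * k * (n + 1/2) / N),

rescaled so that ``dct1 = c_0 / N`` equals the contour mean (in T-value
units) and ``dct2 = c_1 * 2/N``, ``dct3 = c_2 * 2/N``. Under this
convention a rising contour has a negative dct2 and a falling contour a
positive dct2; a U-shaped contour has a positive dct3.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.fft import dct as _scipy_dct

from .core import TONE_ORDER, Group, Tone
from .errors import (
    ClampWarning,
    DegenerateRangeError,
    EmptyInputError,
    IncompleteReferenceError,
    RangeViolationError,
    ValidationError,
)
from .trajectory_io import F0Trajectory, SpeakerRange

__all__ = [
    "TValueTrajectory",
    "DurationStats",
    "DCTFeatures",
    "ToneCentroid",
    "speaker_range",
    "t_normalize",
    "t_denormalize",
    "dct_coefficients",
    "dct_shape",
    "dct_features",
    "duration_stats",
    "tone_centroids",
    "tonal_distance",
]


@dataclass(frozen=True)
class TValueTrajectory:
    """A pitch track on the speaker-relative 0-5 T-value scale."""

    speaker_id: str
    group: Group
    item: str
    tone: Tone
    day: int
    tvals: tuple[float, ...]
    duration_ms: float
    rep: int = 1
    clamped: tuple[int, ...] = ()

    @property
    def key(self) -> tuple:
        return (self.speaker_id, self.day, self.item, self.rep)

    def values(self) -> np.ndarray:
        return np.asarray(self.tvals, dtype=float)


@dataclass(frozen=True)
class DurationStats:
    """Mean/SD of the reference (target) durations used for z-scoring."""

    mean_ms: float
    sd_ms: float

    def __post_init__(self) -> None:
        if self.sd_ms <= 0:
            raise ValidationError(f"duration sd must be > 0, got {self.sd_ms}")

    def z(self, duration_ms: float) -> float:
        return (duration_ms - self.mean_ms) / self.sd_ms


@dataclass(frozen=True)
class DCTFeatures:
    """(dct1, dct2, dct3, dur_z): the 4-D vector used for tonal distances."""

    dct1: float
    dct2: float
    dct3: float
    dur_z: float
    tone: Optional[Tone] = None
    key: Optional[tuple] = None

    def vector(self) -> np.ndarray:
        return np.array([self.dct1, self.dct2, self.dct3, self.dur_z], dtype=float)


@dataclass(frozen=True)
class ToneCentroid:
    """Per-tone mean feature vector of the target stimuli."""

    tone: Tone
    centroid: tuple[float, float, float, float]
    n_targets: int

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValidationError("a centroid needs at least one member token")

    def vector(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def speaker_range(trajectories: Sequence[F0Trajectory]) -> SpeakerRange:
    """Pooled min/max valid F0 over all of one speaker's productions."""
    if not trajectories:
        raise EmptyInputError("no trajectories supplied")
    speaker = trajectories[0].speaker_id
    lo = math.inf
    hi = -math.inf
    for t in trajectories:
        if t.speaker_id != speaker:
            raise ValidationError(
                f"mixed speakers in speaker_range: {speaker!r} vs {t.speaker_id!r}"
            )
        for s in t.samples:
            if s is not None:
                lo = min(lo, s)
                hi = max(hi, s)
    if not math.isfinite(lo):
        raise EmptyInputError(f"speaker {speaker!r} has no valid samples")
    if lo == hi:
        raise DegenerateRangeError(f"speaker {speaker!r} has a flat range at {lo} Hz")
    return SpeakerRange(speaker_id=speaker, xmin=lo, xmax=hi)


def t_normalize(
    traj: F0Trajectory, rng: SpeakerRange, strict: bool = False
) -> TValueTrajectory:
    """Map Hz samples onto the 0-5 T-value scale for the given speaker range.

    Samples outside [xmin, xmax] raise :class:`RangeViolationError` in
    strict mode; otherwise they are clamped to the range limits and their
    positions recorded in ``clamped`` (with a warning).
    """
    x = traj.values()
    if np.isnan(x).any():
        raise ValidationError(f"trial {traj.key}: normalize after repair; null samples present")
    # absorb float round-trip error at the range limits before flagging
    tol = 1e-9
    x = np.where(np.abs(x - rng.xmin) <= tol * rng.xmin, rng.xmin, x)
    x = np.where(np.abs(x - rng.xmax) <= tol * rng.xmax, rng.xmax, x)
    below = x < rng.xmin
    above = x > rng.xmax
    clamped: tuple[int, ...] = ()
    if below.any() or above.any():
        if strict:
            bad = int(np.flatnonzero(below | above)[0])
            raise RangeViolationError(
                f"trial {traj.key}: sample {bad} = {x[bad]:.3f} Hz outside "
                f"[{rng.xmin}, {rng.xmax}]"
            )
        warnings.warn(
            f"trial {traj.key}: {int(below.sum() + above.sum())} sample(s) clamped "
            f"to speaker range",
            ClampWarning,
            stacklevel=2,
        )
        clamped = tuple(np.flatnonzero(below | above).tolist())
        x = np.clip(x, rng.xmin, rng.xmax)
    denom = math.log10(rng.xmax) - math.log10(rng.xmin)
    tvals = 5.0 * (np.log10(x) - math.log10(rng.xmin)) / denom
    # the range limits must map to exactly 0 and 5 regardless of log rounding
    tvals = np.where(x == rng.xmin, 0.0, np.where(x == rng.xmax, 5.0, tvals))
    return TValueTrajectory(
        speaker_id=traj.speaker_id,
        group=traj.group,
        item=traj.item,
        tone=traj.tone,
        day=traj.day,
        tvals=tuple(float(v) for v in tvals),
        duration_ms=traj.duration_ms,
        rep=traj.rep,
        clamped=clamped,
    )


def t_denormalize(tvals: Sequence[float], rng: SpeakerRange) -> np.ndarray:
    """Inverse of :func:`t_normalize`: T-values back to Hz for one speaker."""
    t = np.asarray(tvals, dtype=float)
    log_span = math.log10(rng.xmax) - math.log10(rng.xmin)
    return np.power(10.0, math.log10(rng.xmin) + t / 5.0 * log_span)


# ---------------------------------------------------------------------------
# DCT features
# ---------------------------------------------------------------------------

def dct_coefficients(x: Sequence[float]) -> np.ndarray:
    """All N coefficients c_k = sum_n x_n cos(pi k (n+1/2) / N)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("dct_coefficients expects a non-empty 1-D sequence")
    # scipy's unnormalized DCT-II returns 2 * c_k
    return _scipy_dct(x, type=2, norm=None) / 2.0


def dct_shape(x: Sequence[float]) -> tuple[float, float, float]:
    """(dct1, dct2, dct3) of a contour under the package scaling convention."""
    x = np.asarray(x, dtype=float)
    n = x.size
    c = dct_coefficients(x)
    return float(c[0] / n), float(c[1] * 2.0 / n), float(c[2] * 2.0 / n)


def dct_features(
    traj: TValueTrajectory, dur_stats: DurationStats, expected_length: int = 16
) -> DCTFeatures:
    """Shape coefficients plus z-scored duration for one production."""
    x = traj.values()
    if expected_length is not None and x.size != expected_length:
        raise ValidationError(
            f"trial {traj.key}: expected {expected_length} T-values, got {x.size}"
        )
    d1, d2, d3 = dct_shape(x)
    return DCTFeatures(
        dct1=d1,
        dct2=d2,
        dct3=d3,
        dur_z=dur_stats.z(traj.duration_ms),
        tone=traj.tone,
        key=traj.key,
    )


def duration_stats(durations_ms: Sequence[float]) -> DurationStats:
    """Sample mean/SD (ddof=1) of the reference duration set."""
    d = np.asarray(durations_ms, dtype=float)
    if d.size < 2:
        raise EmptyInputError("need at least 2 reference durations")
    return DurationStats(mean_ms=float(d.mean()), sd_ms=float(d.std(ddof=1)))


# ---------------------------------------------------------------------------
# centroids and distances
# ---------------------------------------------------------------------------

def tone_centroids(target_features: Iterable[DCTFeatures]) -> dict[Tone, ToneCentroid]:
    """Arithmetic mean feature vector of the target tokens, per tone."""
    by_tone: dict[Tone, list[np.ndarray]] = {}
    for f in target_features:
        if f.tone is None:
            raise ValidationError("target feature without a tone label")
        by_tone.setdefault(f.tone, []).append(f.vector())
    missing = [t.value for t in TONE_ORDER if t not in by_tone]
    if missing:
        raise IncompleteReferenceError(f"target set missing tone(s): {', '.join(missing)}")
    out: dict[Tone, ToneCentroid] = {}
    for tone in TONE_ORDER:
        vecs = np.vstack(by_tone[tone])
        out[tone] = ToneCentroid(
            tone=tone,
            centroid=tuple(float(v) for v in vecs.mean(axis=0)),
            n_targets=vecs.shape[0],
        )
    return out


def tonal_distance(features: DCTFeatures, centroid: ToneCentroid) -> float:
    """Euclidean distance of a production's 4-vector from its tone centroid.

    Larger distance = less target-like production.
    """
    f = features.vector()
    c = centroid.vector()
    if not (np.isfinite(f).all() and np.isfinite(c).all()):
        raise ValidationError("tonal_distance requires finite feature vectors")
    return float(np.linalg.norm(f - c))
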
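"""Synthetic stimuli, imitations and naming ledgers for end-to-end testing.

Target contours are built from Chao-numeral tone specifications (digit d on
the 1-5 scale maps to T-value (d-1)*5/4, so 1 -> 0 and 5 -> 5), sampled at
equidistant points and converted to Hz by inverting the T-value transform
for a nominal target-speaker range. Simulated imitations distort the target
in T-space:

    imitation = mean + slope_gain * (target - mean)
                + height_offset * [level tone]
                + curvature_gain * curvature_basis + N(0, noise_sd)

which reproduces the qualitative phenomena the analysis must detect:
compressed contour-tone slopes (slope_gain < 1) and raised level tones
(height_offset > 0). Naming productions are drawn from per-speaker
row-stochastic tone confusion matrices. Everything is deterministic given
the seeds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .core import CHAO_LABEL, LEVEL_TONES, NON_TARGET, TONE_ORDER, Group, Tone
from .errors import ClampWarning, ValidationError
from .lexical_scoring import ProductionLabel
from .tone_metrics import t_denormalize, t_normalize
from .trajectory_io import (
    ExclusionLedger,
    ExclusionReason,
    F0Trajectory,
    SpeakerRange,
)

__all__ = [
    "ToneSpec",
    "SpeakerModel",
    "GroupParams",
    "CohortConfig",
    "CohortResult",
    "DEFAULT_TONE_SPECS",
    "DEFAULT_SEGMENTS",
    "chao_to_t",
    "identity_confusion",
    "make_target_stimuli",
    "simulate_imitations",
    "simulate_naming_ledger",
    "imitation_day_schedule",
    "planned_imitation_ledger",
    "planned_naming_ledger",
    "apply_random_exclusions",
    "default_cohort",
]

#: The four segmental frames crossed with the four tones (4 x 4 = 16 items).
DEFAULT_SEGMENTS: tuple[str, ...] = ("nɔn", "lɔn", "jɑɹ", "juɹ")

#: Nominal pitch range of the (synthetic) target speaker, Hz.
DEFAULT_TARGET_RANGE: tuple[float, float] = (120.0, 300.0)


def chao_to_t(digit: int) -> float:
    """Map a Chao pitch digit (1..5) onto the 0-5 T-value scale."""
    if not 1 <= digit <= 5:
        raise ValidationError(f"Chao digit must be in 1..5, got {digit}")
    return (digit - 1) * 5.0 / 4.0


@dataclass(frozen=True)
class ToneSpec:
    """Chao onset/offset digits plus an optional mid-contour curvature bump.

    ``curvature_gain`` scales a raised-cosine bump that vanishes at the
    contour edges; negative values dip the contour mid-way (a U-shape,
    positive dct3), positive values hump it.
    """

    tone: Tone
    chao_onset: int
    chao_offset: int
    curvature_gain: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.chao_onset, self.chao_offset):
            if not 1 <= d <= 5:
                raise ValidationError(f"Chao digit must be in 1..5, got {d}")
        if self.tone in LEVEL_TONES and self.chao_onset != self.chao_offset:
            raise ValidationError(
                f"level tone {self.tone.value} requires onset == offset, "
                f"got {self.chao_onset}{self.chao_offset}"
            )

    @property
    def chao_label(self) -> str:
        return f"{self.chao_onset}{self.chao_offset}"

    def t_contour(self, n_points: int = 20) -> np.ndarray:
        """T-value contour at ``n_points`` equidistant samples (edges included)."""
        u = np.linspace(0.0, 1.0, n_points)
        on, off = chao_to_t(self.chao_onset), chao_to_t(self.chao_offset)
        bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        return on + (off - on) * u + self.curvature_gain * bump


DEFAULT_TONE_SPECS: tuple[ToneSpec, ...] = (
    ToneSpec(Tone.RISE, 1, 5, curvature_gain=-0.4),
    ToneSpec(Tone.FALL, 5, 1, curvature_gain=-0.4),
    ToneSpec(Tone.MID, 2, 2),
    ToneSpec(Tone.LOW, 1, 1),
)


def identity_confusion() -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(1.0 if i == j else 0.0 for j in range(4)) for i in range(4))


@dataclass(frozen=True)
class SpeakerModel:
    """Generative parameters of one simulated speaker."""

    speaker_id: str
    group: Group
    f0_floor: float
    f0_ceiling: float
    height_offset: float = 0.0  # T-value raise applied to level-tone imitations
    slope_gain: float = 1.0  # contour compression, in (0, 1]
    curvature_gain: float = 0.0  # extra curvature added along the DCT k=2 basis
    noise_sd: float = 0.0  # white noise in T-value units
    duration_jitter_sd: float = 0.0  # sd of log duration multiplier
    confusion_matrix: tuple[tuple[float, ...], ...] = field(default_factory=identity_confusion)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group.parse(self.group))
        if not 0 < self.f0_floor < self.f0_ceiling:
            raise ValidationError("need 0 < f0_floor < f0_ceiling")
        if not 0 < self.slope_gain <= 1.0:
            raise ValidationError(f"slope_gain must be in (0, 1], got {self.slope_gain}")
        if self.noise_sd < 0 or self.duration_jitter_sd < 0:
            raise ValidationError("noise parameters must be non-negative")
        cm = np.asarray(self.confusion_matrix, dtype=float)
        if cm.shape != (4, 4) or (cm < 0).any():
            raise ValidationError("confusion_matrix must be 4x4 and non-negative")
        if not np.allclose(cm.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("confusion_matrix rows must each sum to 1")
        object.__setattr__(
            self, "confusion_matrix", tuple(tuple(float(v) for v in row) for row in cm)
        )

    @property
    def range(self) -> SpeakerRange:
        return SpeakerRange(self.speaker_id, self.f0_floor, self.f0_ceiling)

    def confusion(self) -> np.ndarray:
        return np.asarray(self.confusion_matrix, dtype=float)


# ---------------------------------------------------------------------------
# target stimuli
# ---------------------------------------------------------------------------

def make_target_stimuli(
    specs: Sequence[ToneSpec] = DEFAULT_TONE_SPECS,
    segments: Sequence[str] = DEFAULT_SEGMENTS,
    n_points: int = 20,
    target_range: tuple[float, float] = DEFAULT_TARGET_RANGE,
    speaker_id: str = "target",
) -> list[F0Trajectory]:
    """Cross segment frames with tone specs into target F0 trajectories."""
    rng = SpeakerRange(speaker_id, *target_range)
    out: list[F0Trajectory] = []
    for seg in segments:
        for ti, spec in enumerate(specs):
            t = spec.t_contour(n_points)
            if (t < 0).any() or (t > 5).any():
                warnings.warn(
                    f"target contour {seg}{spec.chao_label} exits [0, 5]; clamped",
                    ClampWarning,
                    stacklevel=2,
                )
                t = np.clip(t, 0.0, 5.0)
            hz = t_denormalize(t, rng)
            out.append(
                F0Trajectory(
                    speaker_id=speaker_id,
                    group=Group.TARGET,
                    item=f"{seg}{spec.chao_label}",
                    tone=spec.tone,
                    day=1,
                    # duration varies by tone only, so that each tone centroid's
                    # dur_z equals its member tokens' dur_z exactly
                    samples=tuple(float(v) for v in hz),
                    duration_ms=400.0 + 24.0 * ti,
                )
            )
    return out


def _curvature_basis(n: int) -> np.ndarray:
    """Unit DCT-II k=2 basis: adds exactly its gain to dct3 (pre-truncation)."""
    return np.cos(np.pi * 2.0 * (np.arange(n) + 0.5) / n)


# ---------------------------------------------------------------------------
# imitations
# ---------------------------------------------------------------------------

def simulate_imitations(
    targets: Sequence[F0Trajectory],
    model: SpeakerModel,
    reps: int = 2,
    days: Sequence[int] = (1, 2),
    target_range: Optional[SpeakerRange] = None,
) -> list[F0Trajectory]:
    """Simulate one speaker's imitations of the target stimuli.

    Deterministic given ``model.seed``; loop order is day > target > rep.
    Distorted contours leaving (0, 5) are clamped with a warning.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if target_range is None:
        from .tone_metrics import speaker_range as _sr

        target_range = _sr(list(targets))
    rng = np.random.default_rng([model.seed, 0])
    basis_cache: dict[int, np.ndarray] = {}
    out: list[F0Trajectory] = []
    n_clamped = 0
    for day in days:
        for target in targets:
            t_target = np.asarray(t_normalize(target, target_range).tvals)
            n = t_target.size
            basis = basis_cache.setdefault(n, _curvature_basis(n))
            mean = float(t_target.mean())
            shape = mean + model.slope_gain * (t_target - mean)
            if target.tone in LEVEL_TONES:
                shape = shape + model.height_offset
            shape = shape + model.curvature_gain * basis
            for rep in range(1, reps + 1):
                t = shape + rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else shape.copy()
                if (t < 0).any() or (t > 5).any():
                    n_clamped += 1
                    t = np.clip(t, 0.0, 5.0)
                hz = t_denormalize(t, model.range)
                factor = (
                    float(np.exp(rng.normal(0.0, model.duration_jitter_sd)))
                    if model.duration_jitter_sd > 0
                    else 1.0
                )
                out.append(
                    F0Trajectory(
                        speaker_id=model.speaker_id,
                        group=model.group,
                        item=target.item,
                        tone=target.tone,
                        day=day,
                        samples=tuple(float(v) for v in hz),
                        duration_ms=target.duration_ms * factor,
                        rep=rep,
                    )
                )
    if n_clamped:
        warnings.warn(
            f"speaker {model.speaker_id}: {n_clamped} imitation contour(s) clamped to (0, 5)",
            ClampWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# picture naming
# ---------------------------------------------------------------------------

def simulate_naming_ledger(
    model: SpeakerModel,
    targets: Sequence[F0Trajectory],
    days: Sequence[int] = (1, 2),
    p_segment_correct: "float | Mapping[int, float]" = 0.8,
    p_non_target_given_error: float = 0.2,
) -> list[ProductionLabel]:
    """Draw one speaker's picture-naming labels from the confusion model.

    Segments are produced correctly with probability ``p_segment_correct``
    (optionally per day); incorrect segment productions are either another
    segment frame from the inventory or a deviant non-target string. The
    produced tone is always drawn from the confusion row of the target tone.
    """
    probs = dict(p_segment_correct) if isinstance(p_segment_correct, Mapping) else {
        d: float(p_segment_correct) for d in days
    }
    for d in days:
        if not 0.0 <= probs[d] <= 1.0:
            raise ValidationError(f"p_segment_correct[{d}] must be a probability")
    if not 0.0 <= p_non_target_given_error <= 1.0:
        raise ValidationError("p_non_target_given_error must be a probability")
    rng = np.random.default_rng([model.seed, 1])
    cm = model.confusion()
    tone_index = {t: i for i, t in enumerate(TONE_ORDER)}
    segments = sorted({tgt.item[: -2] for tgt in targets})
    out: list[ProductionLabel] = []
    for day in days:
        for target in targets:
            target_seg = target.item[:-2]
            if rng.random() < probs[day]:
                produced_seg = target_seg
            elif rng.random() < p_non_target_given_error:
                produced_seg = NON_TARGET
            else:
                others = [s for s in segments if s != target_seg]
                produced_seg = others[int(rng.integers(len(others)))]
            produced_tone = TONE_ORDER[
                int(rng.choice(4, p=cm[tone_index[target.tone]]))
            ]
            out.append(
                ProductionLabel(
                    speaker_id=model.speaker_id,
                    group=model.group,
                    day=day,
                    item=target.item,
                    target_segments=target_seg,
                    target_tone=target.tone,
                    produced_segments=produced_seg,
                    produced_tone=produced_tone,
                )
            )
    return out


# ---------------------------------------------------------------------------
# schedules and planned-design ledgers
# ---------------------------------------------------------------------------

def _shares_dimension(a: F0Trajectory, b: F0Trajectory) -> bool:
    return a.item[:-2] == b.item[:-2] or a.tone == b.tone


def imitation_day_schedule(
    targets: Sequence[F0Trajectory],
    presentations: int = 4,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 1000,
) -> list[str]:
    """One participant-day trial list: each stimulus ``presentations`` times.

    The first two presentations run in paired order (each stimulus twice in
    a row, with no segmental or tonal minimal pair across neighbouring
    stimuli); remaining presentations are fully randomized.
    """
    if presentations < 2:
        raise ValidationError("presentations must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    segs = sorted({t.item[:-2] for t in targets})
    tones = sorted({t.tone for t in targets}, key=lambda t: t.value)
    by_cell = {(t.item[:-2], t.tone): t for t in targets}
    if len(by_cell) != len(segs) * len(tones) or len(by_cell) != len(targets):
        raise ValidationError("schedule needs a full segment x tone crossing")
    order = None
    for _ in range(max_tries):
        # a randomized Latin-square walk: both the segment and the tone index
        # change at every step, so no segmental or tonal minimal pair is adjacent
        sp = rng.permutation(len(segs))
        tp = rng.permutation(len(tones))
        cand = [
            by_cell[(segs[sp[k % len(segs)]], tones[tp[(k + k // len(segs)) % len(tones)]])]
            for k in range(len(targets))
        ]
        if all(not _shares_dimension(cand[i], cand[i + 1]) for i in range(len(cand) - 1)):
            order = cand
            break
    if order is None:
        raise ValidationError("could not satisfy the minimal-pair ordering constraint")
    trials: list[str] = []
    for t in order:
        trials.extend([t.item, t.item])  # paired presentation block
    tail = [t.item for t in targets for _ in range(presentations - 2)]
    trials.extend(np.array(tail)[rng.permutation(len(tail))].tolist())
    return trials


def planned_imitation_ledger(
    speaker_ids: Optional[Sequence[str]] = None,
    n_speakers: int = 41,
    items: Optional[Sequence[str]] = None,
    n_words: int = 16,
    reps: int = 2,
    days: Sequence[int] = (1, 2),
) -> ExclusionLedger:
    """Planned imitation design: reps x words x speakers x days trial keys."""
    if speaker_ids is None:
        speaker_ids = [f"s{i:02d}" for i in range(1, n_speakers + 1)]
    if items is None:
        items = [f"w{i:02d}" for i in range(1, n_words + 1)]
    planned = [
        (spk, day, item, rep)
        for spk in speaker_ids
        for day in days
        for item in items
        for rep in range(1, reps + 1)
    ]
    return ExclusionLedger(planned=planned)


def planned_naming_ledger(
    speaker_ids: Optional[Sequence[str]] = None,
    n_speakers: int = 41,
    items: Optional[Sequence[str]] = None,
    n_words: int = 16,
    days: Sequence[int] = (1, 2),
) -> ExclusionLedger:
    """Planned picture-naming design: words x speakers x days trial keys."""
    if speaker_ids is None:
        speaker_ids = [f"s{i:02d}" for i in range(1, n_speakers + 1)]
    if items is None:
        items = [f"w{i:02d}" for i in range(1, n_words + 1)]
    planned = [
        (spk, day, item) for spk in speaker_ids for day in days for item in items
    ]
    return ExclusionLedger(planned=planned)


def apply_random_exclusions(
    ledger: ExclusionLedger,
    n_excluded: int,
    rng: np.random.Generator,
    reasons: Sequence[ExclusionReason] = (
        ExclusionReason.RECORDING_ERROR,
        ExclusionReason.NON_RESPONSE,
    ),
) -> ExclusionLedger:
    """Exclude ``n_excluded`` uniformly drawn planned trials, cycling reasons."""
    if n_excluded > ledger.planned_count:
        raise ValidationError("cannot exclude more trials than planned")
    picks = rng.choice(ledger.planned_count, size=n_excluded, replace=False)
    for j, i in enumerate(sorted(int(v) for v in picks)):
        ledger.exclude(ledger.planned[i], reasons[j % len(reasons)])
    return ledger


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Distributions from which one group's speaker models are drawn."""

    n_speakers: int
    height_offset_mean: float = 0.0
    height_offset_sd: float = 0.0
    slope_gain_mean: float = 1.0
    slope_gain_sd: float = 0.0
    curvature_gain_mean: float = 0.0
    curvature_gain_sd: float = 0.0
    noise_sd: float = 0.2
    duration_jitter_sd: float = 0.04
    f0_floor_low: float = 90.0
    f0_floor_high: float = 180.0
    range_ratio_low: float = 1.9
    range_ratio_high: float = 2.6
    confusion_matrix: tuple[tuple[float, ...], ...] = field(default_factory=identity_confusion)


def _near_uniform_confusion(diag: float = 0.82) -> tuple[tuple[float, ...], ...]:
    off = (1.0 - diag) / 3.0
    return tuple(
        tuple(diag if i == j else off for j in range(4)) for i in range(4)
    )


def _low_to_mid_confusion() -> tuple[tuple[float, ...], ...]:
    rows = [
        [0.85, 0.05, 0.05, 0.05],  # rise
        [0.05, 0.85, 0.05, 0.05],  # fall
        [0.04, 0.04, 0.84, 0.08],  # mid
        [0.03, 0.03, 0.34, 0.60],  # low: errors dominated by low -> mid
    ]
    return tuple(tuple(v for v in row) for row in rows)


DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "english": GroupParams(
        n_speakers=21,
        height_offset_mean=0.25,
        height_offset_sd=0.08,
        slope_gain_mean=0.72,
        slope_gain_sd=0.06,
        noise_sd=0.25,
        confusion_matrix=_near_uniform_confusion(),
    ),
    "mandarin": GroupParams(
        n_speakers=20,
        height_offset_mean=0.65,
        height_offset_sd=0.10,
        slope_gain_mean=0.78,
        slope_gain_sd=0.06,
        noise_sd=0.25,
        confusion_matrix=_low_to_mid_confusion(),
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_points: int = 20
    imitation_reps: int = 2
    days: tuple[int, ...] = (1, 2)
    target_range: tuple[float, float] = DEFAULT_TARGET_RANGE
    segments: tuple[str, ...] = DEFAULT_SEGMENTS
    tone_specs: tuple[ToneSpec, ...] = DEFAULT_TONE_SPECS
    groups: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    p_segment_correct: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.80}
    )
    p_non_target_given_error: float = 0.15
    n_imitation_exclusions: int = 21
    n_naming_exclusions: int = 4

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        data = dict(data)
        if "groups" in data:
            groups = {}
            for name, params in data["groups"].items():
                params = dict(params)
                if "confusion_matrix" in params:
                    params["confusion_matrix"] = tuple(
                        tuple(float(v) for v in row) for row in params["confusion_matrix"]
                    )
                groups[name] = GroupParams(**params)
            data["groups"] = groups
        if "tone_specs" in data:
            data["tone_specs"] = tuple(
                ToneSpec(tone=Tone.parse(s["tone"]), chao_onset=int(s["chao_onset"]),
                         chao_offset=int(s["chao_offset"]),
                         curvature_gain=float(s.get("curvature_gain", 0.0)))
                for s in data["tone_specs"]
            )
        if "p_segment_correct" in data:
            data["p_segment_correct"] = {
                int(k): float(v) for k, v in data["p_segment_correct"].items()
            }
        for key in ("days", "segments", "target_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CohortResult:
    config: CohortConfig
    targets: list[F0Trajectory]
    target_range: SpeakerRange
    speaker_models: dict[str, SpeakerModel]
    imitations: list[F0Trajectory]
    imitation_ledger: ExclusionLedger
    naming_labels: list[ProductionLabel]
    naming_ledger: ExclusionLedger

    def ground_truth(self) -> dict:
        """JSON-able sidecar of every generating parameter, for recovery tests."""
        return {
            "seed": self.config.seed,
            "target_range": [self.target_range.xmin, self.target_range.xmax],
            "speakers": {
                sid: {
                    "group": m.group.value,
                    "f0_floor": m.f0_floor,
                    "f0_ceiling": m.f0_ceiling,
                    "height_offset": m.height_offset,
                    "slope_gain": m.slope_gain,
                    "curvature_gain": m.curvature_gain,
                    "noise_sd": m.noise_sd,
                    "duration_jitter_sd": m.duration_jitter_sd,
                    "confusion_matrix": [list(r) for r in m.confusion_matrix],
                    "seed": m.seed,
                }
                for sid, m in self.speaker_models.items()
            },
        }


def _draw_speaker_model(
    speaker_id: str, group: str, params: GroupParams, rng: np.random.Generator, seed: int
) -> SpeakerModel:
    floor = float(rng.uniform(params.f0_floor_low, params.f0_floor_high))
    ceiling = floor * float(rng.uniform(params.range_ratio_low, params.range_ratio_high))
    gamma = float(
        np.clip(rng.normal(params.slope_gain_mean, params.slope_gain_sd), 0.05, 1.0)
    )
    beta = float(rng.normal(params.height_offset_mean, params.height_offset_sd))
    kappa = float(rng.normal(params.curvature_gain_mean, params.curvature_gain_sd))
    return SpeakerModel(
        speaker_id=speaker_id,
        group=Group.parse(group),
        f0_floor=floor,
        f0_ceiling=ceiling,
        height_offset=beta,
        slope_gain=gamma,
        curvature_gain=kappa,
        noise_sd=params.noise_sd,
        duration_jitter_sd=params.duration_jitter_sd,
        confusion_matrix=params.confusion_matrix,
        seed=seed,
    )


def default_cohort(config: CohortConfig = CohortConfig()) -> CohortResult:
    """Generate the full synthetic experiment (targets, imitations, naming)."""
    master = np.random.default_rng(config.seed)
    targets = make_target_stimuli(
        specs=config.tone_specs,
        segments=config.segments,
        n_points=config.n_points,
        target_range=config.target_range,
    )
    target_range = SpeakerRange("target", *config.target_range)

    speaker_models: dict[str, SpeakerModel] = {}
    idx = 0
    for group_name in sorted(config.groups):
        params = config.groups[group_name]
        for _ in range(params.n_speakers):
            idx += 1
            sid = f"{group_name[:3]}{idx:02d}"
            speaker_models[sid] = _draw_speaker_model(
                sid, group_name, params, master, seed=config.seed * 100_000 + idx
            )

    speaker_ids = list(speaker_models)
    items = [t.item for t in targets]
    imitation_ledger = planned_imitation_ledger(
        speaker_ids=speaker_ids, items=items, reps=config.imitation_reps, days=config.days
    )
    apply_random_exclusions(imitation_ledger, config.n_imitation_exclusions, master)
    naming_ledger = planned_naming_ledger(
        speaker_ids=speaker_ids, items=items, days=config.days
    )
    apply_random_exclusions(
        naming_ledger,
        config.n_naming_exclusions,
        master,
        reasons=(ExclusionReason.BAD_QUALITY, ExclusionReason.NON_RESPONSE),
    )

    imitations: list[F0Trajectory] = []
    for sid in speaker_ids:
        trajs = simulate_imitations(
            targets,
            speaker_models[sid],
            reps=config.imitation_reps,
            days=config.days,
            target_range=target_range,
        )
        imitations.extend(t for t in trajs if not imitation_ledger.is_excluded(t.key))

    naming_labels: list[ProductionLabel] = []
    for sid in speaker_ids:
        labels = simulate_naming_ledger(
            speaker_models[sid],
            targets,
            days=config.days,
            p_segment_correct=config.p_segment_correct,
            p_non_target_given_error=config.p_non_target_given_error,
        )
        for lb in labels:
            if naming_ledger.is_excluded(lb.key):
                lb = replace(lb, quality_flag=True)
            naming_labels.append(lb)

    return CohortResult(
        config=config,
        targets=targets,
        target_range=target_range,
        speaker_models=speaker_models,
        imitations=imitations,
        imitation_ledger=imitation_ledger,
        naming_labels=naming_labels,
        naming_ledger=naming_ledger,
    )
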
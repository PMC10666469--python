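"""Config-driven orchestration: ingest -> repair -> truncate -> normalize ->
DCT -> distance -> cluster -> score -> summarize, with deterministic seeding
and run manifests."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import TONE_ORDER, Group, Tone
from .errors import EmptyInputError, IncompleteReferenceError, ValidationError
from .lexical_scoring import (
    NamingOutcome,
    ProductionLabel,
    read_label_ledger,
    score_ledger,
    summarize_accuracy,
    tabulate_errors,
)
from .synthetic_data import CohortConfig, CohortResult, default_cohort
from .tone_metrics import (
    DCTFeatures,
    dct_features,
    duration_stats,
    speaker_range,
    t_normalize,
    tonal_distance,
    tone_centroids,
)
from .trajectory_io import (
    ExclusionLedger,
    ExclusionReason,
    F0Trajectory,
    IrreparableContourError,
    SpeakerRange,
    TableDialect,
    read_normtime_table,
    repair_contour,
    truncate_edges,
)

__all__ = ["RunConfig", "ImitationResult", "NamingResult",
           "run_imitation_analysis", "run_naming_analysis", "bootstrap_mean_ci"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one analysis run.

    Exactly one of ``simulate`` and ``input_table`` must be set. With file
    input, ``target_table``/``naming_ledger`` supply the reference stimuli
    and picture-naming labels.
    """

    simulate: Optional[CohortConfig] = None
    input_table: Optional[str] = None
    target_table: Optional[str] = None
    naming_ledger: Optional[str] = None
    dialect: TableDialect = field(default_factory=TableDialect)
    jump_ratio: float = 1.8
    n_drop: int = 2
    strict_range: bool = False
    range_source: str = "data"  # "data" | "ground_truth" (simulate mode only)
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_table is None and self.naming_ledger is None):
            raise ValidationError(
                "exactly one of a simulate block and file inputs must be configured"
            )
        if self.bootstrap_reps < 0:
            raise ValidationError("bootstrap_reps must be >= 0")
        if self.range_source not in {"data", "ground_truth"}:
            raise ValidationError(f"unknown range_source {self.range_source!r}")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "simulate" in data and data["simulate"] is not None:
            data["simulate"] = CohortConfig.from_dict(data["simulate"])
        if "dialect" in data:
            data["dialect"] = TableDialect(**data["dialect"])
        return cls(**data)

    def config_hash(self) -> str:
        def _default(o):
            if is_dataclass(o) and not isinstance(o, type):
                return asdict(o)
            if isinstance(o, Mapping):
                return dict(o)
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, counts: Mapping[str, int]) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": dict(counts),
    }


@dataclass
class ImitationResult:
    features: pd.DataFrame  # one row per production: metadata + coefficients + distance
    summary: pd.DataFrame  # group x tone x day mean distance with bootstrap CI
    centroids: dict[Tone, object]
    ledger: ExclusionLedger
    manifest: dict

    def write(self, out_dir: "str | Path") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "distance_summary.tsv", sep="\t", index=False)
        self.ledger.write_tsv(out / "exclusions.tsv")
        centroid_map = {
            tone.value: {"centroid": list(c.centroid), "n_targets": c.n_targets}
            for tone, c in self.centroids.items()
        }
        (out / "centroids.json").write_text(json.dumps(centroid_map, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _prepare(
    trajs: Sequence[F0Trajectory],
    ledger: ExclusionLedger,
    jump_ratio: float,
    n_drop: int,
) -> list[F0Trajectory]:
    """Repair then truncate; irreparable trials go to the ledger."""
    out = []
    for t in trajs:
        try:
            fixed = repair_contour(t, jump_ratio=jump_ratio).trajectory
        except IrreparableContourError:
            ledger.exclude(t.key, ExclusionReason.RECORDING_ERROR)
            continue
        out.append(truncate_edges(fixed, n_drop=n_drop))
    return out


def run_imitation_analysis(config: RunConfig) -> ImitationResult:
    """Per-production DCT features and tonal distances plus condition summary."""
    gt_ranges: dict[str, SpeakerRange] = {}
    if config.simulate is not None:
        cohort = default_cohort(config.simulate)
        targets, imitations = cohort.targets, cohort.imitations
        ledger = cohort.imitation_ledger
        if config.range_source == "ground_truth":
            gt_ranges = {sid: m.range for sid, m in cohort.speaker_models.items()}
            gt_ranges["target"] = cohort.target_range
    else:
        if config.target_table is None or config.input_table is None:
            raise ValidationError("file mode needs input_table and target_table")
        if config.range_source == "ground_truth":
            raise ValidationError("ground_truth ranges are only available in simulate mode")
        targets, _ = read_normtime_table(config.target_table, config.dialect)
        imitations, ledger = read_normtime_table(config.input_table, config.dialect)

    targets = _prepare(targets, planned_passthrough(targets), config.jump_ratio, config.n_drop)
    imitations = _prepare(imitations, ledger, config.jump_ratio, config.n_drop)
    logger.info("prepared %d targets, %d imitations", len(targets), len(imitations))

    present = {t.tone for t in targets}
    missing = [t.value for t in TONE_ORDER if t not in present]
    if missing:
        raise IncompleteReferenceError(f"target set missing tone(s): {', '.join(missing)}")

    target_rng = gt_ranges.get("target") or speaker_range(targets)
    dstats = duration_stats([t.duration_ms for t in targets])
    target_feats = [
        dct_features(t_normalize(t, target_rng, strict=config.strict_range), dstats)
        for t in targets
    ]
    centroids = tone_centroids(target_feats)

    by_speaker: dict[str, list[F0Trajectory]] = {}
    for t in imitations:
        by_speaker.setdefault(t.speaker_id, []).append(t)

    rows = []
    for sid, trajs in by_speaker.items():
        rng = gt_ranges.get(sid) or speaker_range(trajs)
        for t in trajs:
            feats = dct_features(t_normalize(t, rng, strict=config.strict_range), dstats)
            dist = tonal_distance(feats, centroids[t.tone])
            rows.append(
                {
                    "speaker": sid,
                    "group": t.group.value,
                    "item": t.item,
                    "tone": t.tone.value,
                    "day": t.day,
                    "rep": t.rep,
                    "dct1": feats.dct1,
                    "dct2": feats.dct2,
                    "dct3": feats.dct3,
                    "dur_z": feats.dur_z,
                    "distance": dist,
                }
            )
    features = pd.DataFrame(rows).sort_values(
        ["group", "speaker", "day", "item", "rep"], kind="stable"
    ).reset_index(drop=True)

    boot_rng = np.random.default_rng([config.seed, 2])
    summary_rows = []
    for (group, tone, day), sub in features.groupby(["group", "tone", "day"], sort=True):
        vals = sub["distance"].to_numpy()
        if len(vals) >= 2 and config.bootstrap_reps >= 100:
            mean, lo, hi = bootstrap_mean_ci(
                vals, reps=config.bootstrap_reps,
                seed=int(boot_rng.integers(2**31)),
            )
        else:
            mean, lo, hi = float(np.mean(vals)), np.nan, np.nan
        summary_rows.append(
            {"group": group, "tone": tone, "day": day, "n": len(vals),
             "mean_distance": mean, "ci_lo": lo, "ci_hi": hi}
        )
    summary = pd.DataFrame(summary_rows)

    manifest = _manifest(
        config,
        {
            "targets": len(targets),
            "planned": ledger.planned_count,
            "excluded": ledger.excluded_count,
            "retained": ledger.retained_count,
            "feature_rows": len(features),
        },
    )
    return ImitationResult(
        features=features, summary=summary, centroids=centroids,
        ledger=ledger, manifest=manifest,
    )


def planned_passthrough(trajs: Sequence[F0Trajectory]) -> ExclusionLedger:
    """A ledger whose planned design is exactly the given trials."""
    return ExclusionLedger(planned=[t.key for t in trajs])


@dataclass
class NamingResult:
    outcomes: pd.DataFrame
    error_tables: dict[tuple, pd.DataFrame]
    speaker_summary: pd.DataFrame
    group_summary: pd.DataFrame
    ledger: ExclusionLedger
    manifest: dict

    def write(self, out_dir: "str | Path") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False)
        for gkey, table in self.error_tables.items():
            stem = "_".join(str(g) for g in gkey) or "all"
            table.to_csv(out / f"error_table_{stem}.csv")
        self.speaker_summary.to_csv(out / "speaker_summary.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        self.ledger.write_tsv(out / "exclusions.tsv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def run_naming_analysis(config: RunConfig) -> NamingResult:
    """Score the naming ledger and build error tables and accuracy summaries."""
    if config.simulate is not None:
        cohort = default_cohort(config.simulate)
        labels, ledger = cohort.naming_labels, cohort.naming_ledger
    else:
        if config.naming_ledger is None:
            raise ValidationError("file mode needs a naming_ledger path")
        labels = read_label_ledger(config.naming_ledger)
        ledger = ExclusionLedger(planned=[lb.key for lb in labels])
        for lb in labels:
            if lb.quality_flag:
                ledger.exclude(lb.key, ExclusionReason.BAD_QUALITY)

    outcomes = score_ledger(labels)
    if not outcomes:
        raise EmptyInputError("empty naming ledger")
    out_df = pd.DataFrame(
        [
            {
                "speaker": o.speaker_id,
                "group": o.group.value,
                "day": o.day,
                "item": o.key[2],
                "target_tone": o.target_tone.value,
                "category": o.category.value,
                "error_type": (
                    f"{o.error_type[0].value}-to-{o.error_type[1].value}"
                    if o.error_type
                    else ""
                ),
            }
            for o in outcomes
        ]
    )
    tables = tabulate_errors(outcomes, by=("group",)).tables
    speaker_summary, group_summary = summarize_accuracy(outcomes)
    manifest = _manifest(
        config,
        {
            "planned": ledger.planned_count,
            "excluded": ledger.excluded_count,
            "retained": ledger.retained_count,
            "outcome_rows": len(out_df),
        },
    )
    return NamingResult(
        outcomes=out_df,
        error_tables=tables,
        speaker_summary=speaker_summary,
        group_summary=group_summary,
        ledger=ledger,
        manifest=manifest,
    )


def bootstrap_mean_ci(
    values: Sequence[float], reps: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap 95% CI of the mean; deterministic given seed."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EmptyInputError("bootstrap_mean_ci received no values")
    if x.size < 2:
        raise ValidationError("need at least 2 values to bootstrap a CI")
    if reps < 100:
        raise ValidationError(f"reps must be >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(x.mean()), float(lo), float(hi)
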
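"""Two-cluster disambiguation of level-tone contours (mid vs. low).

Equal-length T-value contours are grouped by hierarchical agglomerative
clustering (Ward linkage on Euclidean distances by default). With k = 2 the
cluster whose members have the higher grand-mean T-value is labelled
``mid``, the other ``low``; assignments are then reconciled against the
prior (rater) labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core import LEVEL_TONES, Tone
from .errors import (
    DegenerateClusteringWarning,
    EmptyInputError,
    InsufficientDataError,
    ValidationError,
)
from .tone_metrics import TValueTrajectory

__all__ = [
    "ClusterAssignment",
    "LabelChange",
    "cluster_level_contours",
    "correspondence_rate",
    "reconcile_labels",
]

#: Midpoint of the T-value scale; used only in the degenerate all-identical case.
_T_SCALE_MIDPOINT = 2.5


@dataclass(frozen=True)
class ClusterAssignment:
    key: tuple
    cluster_index: int
    assigned_level: Tone
    prior_label: Tone
    corresponds: bool


@dataclass(frozen=True)
class LabelChange:
    key: tuple
    old: Tone
    new: Tone


def cluster_level_contours(
    contours: Sequence[TValueTrajectory],
    k: int = 2,
    linkage_method: str = "ward",
) -> list[ClusterAssignment]:
    """Cluster level-tone contours and label the clusters mid vs. low.

    Only k = 2 carries a level labelling; ties on cluster mean height are
    broken by lower within-cluster variance, then by first occurrence.
    Identical contours trigger :class:`DegenerateClusteringWarning` and a
    single mean-height-based category.
    """
    if k != 2:
        raise ValidationError("level-tone disambiguation is defined for k = 2 clusters")
    n = len(contours)
    if n < k:
        raise InsufficientDataError(f"need at least {k} contours, got {n}")
    for c in contours:
        if c.tone not in LEVEL_TONES:
            raise ValidationError(
                f"contour {c.key} has non-level prior label {c.tone.value!r}"
            )
    X = np.vstack([c.values() for c in contours])
    if X.ndim != 2 or len({row.shape for row in X}) > 1:
        raise ValidationError("contours must all have the same length")

    if np.allclose(X, X[0], rtol=0, atol=0):
        warnings.warn(
            "all contours are identical; assigning a single category by mean height",
            DegenerateClusteringWarning,
            stacklevel=2,
        )
        level = Tone.MID if float(X.mean()) >= _T_SCALE_MIDPOINT else Tone.LOW
        labels = np.zeros(n, dtype=int)
        return _build_assignments(contours, labels, {0: level})

    Z = linkage(X, method=linkage_method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1  # 0-based

    stats = []
    for idx in range(k):
        members = X[labels == idx]
        first = int(np.flatnonzero(labels == idx)[0])
        stats.append((float(members.mean()), -float(members.var()), -first, idx))
    # higher mean wins mid; ties: lower variance, then earlier first occurrence
    ranked = sorted(stats, reverse=True)
    level_of = {ranked[0][3]: Tone.MID, ranked[1][3]: Tone.LOW}
    return _build_assignments(contours, labels, level_of)


def _build_assignments(
    contours: Sequence[TValueTrajectory],
    labels: np.ndarray,
    level_of: dict[int, Tone],
) -> list[ClusterAssignment]:
    out = []
    for contour, idx in zip(contours, labels):
        level = level_of[int(idx)]
        out.append(
            ClusterAssignment(
                key=contour.key,
                cluster_index=int(idx),
                assigned_level=level,
                prior_label=contour.tone,
                corresponds=level == contour.tone,
            )
        )
    return out


def correspondence_rate(assignments: Sequence[ClusterAssignment]) -> float:
    """Percentage of prior labels that agree with the cluster-derived labels."""
    if not assignments:
        raise EmptyInputError("no cluster assignments supplied")
    agree = sum(a.corresponds for a in assignments)
    return 100.0 * agree / len(assignments)


def reconcile_labels(
    assignments: Sequence[ClusterAssignment],
) -> tuple[dict[tuple, Tone], list[LabelChange]]:
    """Replace non-corresponding prior labels with the cluster-derived level.

    Returns the updated key -> label ledger and the change log (one entry
    per flipped label). Applying the operation to already-reconciled
    assignments yields an empty change log.
    """
    ledger: dict[tuple, Tone] = {}
    changes: list[LabelChange] = []
    for a in assignments:
        ledger[a.key] = a.assigned_level
        if not a.corresponds:
            changes.append(LabelChange(key=a.key, old=a.prior_label, new=a.assigned_level))
    return ledger, changes
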
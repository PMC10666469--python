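"""Independent oracles and small builders shared across the test suite.

The oracles here deliberately avoid the package's own code paths: the DCT
oracle is a double-loop cosine sum, the distance oracle a component-wise
sum of squares, etc.
"""
from __future__ import annotations

import math

import numpy as np

from tonetrace import F0Trajectory, Group, Tone, TValueTrajectory


def brute_force_dct_shape(x) -> tuple[float, float, float]:
    """Double-loop cosine-sum DCT, rescaled like the package convention."""
    x = list(map(float, x))
    n = len(x)
    coeffs = []
    for k in range(3):
        c = 0.0
        for i, xi in enumerate(x):
            c += xi * math.cos(math.pi * k * (i + 0.5) / n)
        coeffs.append(c)
    return coeffs[0] / n, coeffs[1] * 2.0 / n, coeffs[2] * 2.0 / n


def brute_force_norm(f, c) -> float:
    """Component-wise sum-of-squares Euclidean norm."""
    total = 0.0
    for a, b in zip(f, c):
        total += (a - b) ** 2
    return math.sqrt(total)


def make_traj(samples, speaker="s01", group=Group.ENGLISH, item="w01",
              tone=Tone.RISE, day=1, duration_ms=400.0, rep=1) -> F0Trajectory:
    return F0Trajectory(
        speaker_id=speaker, group=group, item=item, tone=tone, day=day,
        samples=tuple(samples), duration_ms=duration_ms, rep=rep,
    )


def make_tval(tvals, speaker="s01", group=Group.ENGLISH, item="w01",
              tone=Tone.MID, day=1, duration_ms=400.0, rep=1) -> TValueTrajectory:
    return TValueTrajectory(
        speaker_id=speaker, group=group, item=item, tone=tone, day=day,
        tvals=tuple(float(v) for v in tvals), duration_ms=duration_ms, rep=rep,
    )


def level_contours(mean, n, noise_sd, rng, tone=Tone.MID, length=16, speaker="s01"):
    """Flat level-tone contours at the given mean with white noise."""
    out = []
    for i in range(n):
        vals = np.clip(mean + rng.normal(0.0, noise_sd, size=length), 0.0, 5.0)
        out.append(
            make_tval(vals, speaker=speaker, item=f"{tone.value}{i:03d}", tone=tone)
        )
    return out
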
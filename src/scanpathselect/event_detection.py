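"""Velocity-threshold identification (I-VT) of fixations and saccades.

The classifier is the classic point-to-point formulation: the angular speed
between two consecutive gaze samples is compared against a single velocity
threshold; speeds strictly below the threshold mark fixation samples,
speeds at or above it mark saccadic movement.  Maximal fixation runs
shorter than a minimum duration (default 60 ms, the common I-VT default)
are discarded and their span is counted as saccade time.  Pairs separated
by missing samples are gaps: they carry no speed and always break runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .gaze_io import GazeRecording

__all__ = [
    "FIXATION",
    "SACCADE",
    "GAP",
    "VelocityTrace",
    "Fixation",
    "Saccade",
    "compute_velocities",
    "classify_samples",
    "detect_fixations",
    "events_frame",
]

# Per-pair labels.  Integer codes keep classification fully vectorised.
FIXATION: int = 0
SACCADE: int = 1
GAP: int = 2

#: Default minimum fixation duration in milliseconds.
DEFAULT_MIN_FIX_MS: float = 60.0


@dataclass(frozen=True)
class VelocityTrace:
    """Per-pair angular speeds aligned to consecutive sample pairs.

    ``speed[i]`` is the dva/s speed between samples i and i+1 when both are
    valid; gap-flagged pairs (either endpoint missing) hold NaN and
    contribute no speed value anywhere downstream.
    """

    t: np.ndarray  # sample timestamps (ms), length n
    speed: np.ndarray  # length n-1, NaN where gap
    gap: np.ndarray  # bool, length n-1

    @property
    def n_pairs(self) -> int:
        return int(self.speed.size)


@dataclass(frozen=True)
class Fixation:
    """A classified eye fixation: interval, centroid, and sample count."""

    onset: float
    offset: float
    centroid_x: float
    centroid_y: float
    n_samples: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Saccade:
    """A classified saccadic interval between fixations."""

    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def compute_velocities(rec: GazeRecording) -> VelocityTrace:
    """Point-to-point angular speed between consecutive valid samples.

    Speed is the planar Euclidean dva distance divided by the time step in
    seconds.  Positions are already angles and target eccentricities are
    small, so no spherical correction is applied.
    """
    t, x, y, valid = rec.t, rec.x, rec.y, rec.valid
    if t.size < 2:
        empty = np.empty(0)
        return VelocityTrace(t=t, speed=empty, gap=np.empty(0, dtype=bool))
    pair_ok = valid[:-1] & valid[1:]
    dt_s = np.diff(t) / 1000.0
    dx = np.diff(x)
    dy = np.diff(y)
    speed = np.full(t.size - 1, np.nan)
    np.divide(np.hypot(dx, dy), dt_s, out=speed, where=pair_ok)
    return VelocityTrace(t=t, speed=speed, gap=~pair_ok)


def classify_samples(trace: VelocityTrace, threshold: float) -> np.ndarray:
    """Label each pair FIXATION (speed < threshold), SACCADE, or GAP.

    The inequality is strict for fixations: a speed exactly at the
    threshold is saccadic movement.
    """
    if not threshold > 0:
        raise DomainError(f"velocity threshold must be positive, got {threshold}")
    labels = np.where(trace.speed < threshold, FIXATION, SACCADE).astype(np.int8)
    labels[trace.gap] = GAP
    return labels


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs: (start_pair, end_pair_inclusive, value)."""
    if labels.size == 0:
        z = np.empty(0, dtype=int)
        return z, z, z
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    return starts, ends, labels[starts]


def detect_fixations(
    rec: GazeRecording,
    threshold: float,
    min_fix_ms: float = DEFAULT_MIN_FIX_MS,
    *,
    trace: VelocityTrace | None = None,
) -> tuple[list[Fixation], list[Saccade]]:
    """Run I-VT on a recording at one velocity threshold.

    A maximal run of k fixation-labelled pairs spans k+1 samples; its
    duration is measured onset-to-offset over the member samples'
    timestamps and candidates shorter than ``min_fix_ms`` are discarded
    (their span is relabelled saccade time).  Gaps break runs on both
    sides and belong to neither event class.
    """
    if min_fix_ms < 0:
        raise DomainError("min_fix_ms must be non-negative")
    if trace is None:
        trace = compute_velocities(rec)
    labels = classify_samples(trace, threshold)
    starts, ends, values = _runs(labels)

    fixations: list[Fixation] = []
    kept = np.zeros(labels.size, dtype=bool)
    t, x, y = rec.t, rec.x, rec.y
    fix_mask = values == FIXATION
    if np.any(fix_mask):
        fs, fe = starts[fix_mask], ends[fix_mask]
        durations = t[fe + 1] - t[fs]
        ok = durations >= min_fix_ms
        # Per-run centroids over member samples (pairs s..e span samples
        # s..e+1, all valid because the pairs are not gap-flagged).
        for s, e in zip(fs[ok], fe[ok]):
            sl = slice(s, e + 2)
            fixations.append(
                Fixation(
                    onset=float(t[s]),
                    offset=float(t[e + 1]),
                    centroid_x=float(np.mean(x[sl])),
                    centroid_y=float(np.mean(y[sl])),
                    n_samples=int(e + 2 - s),
                )
            )
            kept[s : e + 1] = True

    # Everything that is not a kept fixation pair and not a gap is saccade
    # time, including discarded sub-minimum fixation candidates.
    final = np.where(labels == GAP, GAP, np.where(kept, FIXATION, SACCADE))
    s2, e2, v2 = _runs(final.astype(np.int8))
    saccades = [
        Saccade(onset=float(t[s]), offset=float(t[e + 1]))
        for s, e, v in zip(s2, e2, v2)
        if v == SACCADE
    ]
    return fixations, saccades


def events_frame(
    fixations: list[Fixation], saccades: list[Saccade]
) -> pd.DataFrame:
    """Events as a time-ordered DataFrame in the export dialect."""
    rows = [
        {
            "event_type": "fixation",
            "onset_ms": f.onset,
            "offset_ms": f.offset,
            "centroid_x": f.centroid_x,
            "centroid_y": f.centroid_y,
            "n_samples": f.n_samples,
        }
        for f in fixations
    ] + [
        {
            "event_type": "saccade",
            "onset_ms": s.onset,
            "offset_ms": s.offset,
            "centroid_x": np.nan,
            "centroid_y": np.nan,
            "n_samples": 0,
        }
        for s in saccades
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "event_type",
            "onset_ms",
            "offset_ms",
            "centroid_x",
            "centroid_y",
            "n_samples",
        ],
    )
    return frame.sort_values("onset_ms", kind="stable").reset_index(drop=True)
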
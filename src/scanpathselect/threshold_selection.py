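"""Threshold sweeps, similarity trends, and velocity-threshold selection.

Given a cohort of recordings, the I-VT pipeline is run over a grid of
gaze-velocity thresholds (default 10-400 deg/s in steps of 10) and each
(threshold, participant) cell yields one scan-path token sequence.  Three
per-threshold trends are derived from that sweep:

* **between-participant** similarity: at threshold i, the mean string-edit
  similarity over all m = p(p-1)/2 unordered participant pairs,

      hbar_i = (1/m) * sum_{(x_j, x_k)} S(x_j, x_k);

* **within-participant** similarity: for participant j, the mean
  similarity of threshold i's sequence to the sequence at every *other*
  threshold (self-comparison excluded, divisor t-1),

      v_ij = (1/(t-1)) * sum_{l != i} S(f_i, f_l),

  averaged over participants, vbar_i = (1/p) * sum_j v_ij;

* **ideal** similarity: the mean over participants of the similarity to
  the known ideal sequence, when one exists.

An accurate threshold range is the contiguous plateau of high, stable
trend values around the argmax; trend agreement is quantified by Spearman
rank correlation.  The between/within trends require no knowledge of the
ideal sequence, which is the point: they let a study select a threshold
when the true scan path is unknown.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .event_detection import DEFAULT_MIN_FIX_MS, compute_velocities, detect_fixations
from .gaze_io import GazeRecording
from .scanpath import DEFAULT_AOI_RADIUS, ScanPathSequence, build_aois, map_fixations

__all__ = [
    "default_grid",
    "SweepResult",
    "SimilarityTrend",
    "RangeSelection",
    "threshold_sweep",
    "between_trend",
    "within_trend",
    "ideal_trend",
    "select_range",
    "trend_correlation",
    "benchmark_compare",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTA: float = 0.05
DEFAULT_BENCHMARK: float = 30.0


def default_grid() -> np.ndarray:
    """The standard sweep grid: 10 to 400 deg/s in increments of 10."""
    return np.arange(10.0, 401.0, 10.0)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("threshold grid must be a nonempty 1-D array")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValidationError("threshold grid must be strictly increasing and positive")
    return grid


@dataclass(frozen=True)
class SweepResult:
    """Token sequences for every (threshold, participant) cell.

    ``sequences[i][j]`` is participant j's scan-path sequence at grid
    threshold i (possibly empty).  The grid is complete: every cell holds
    a sequence.
    """

    grid: np.ndarray
    participant_ids: tuple[str, ...]
    sequences: tuple[tuple[ScanPathSequence, ...], ...]

    @property
    def t(self) -> int:
        """Number of thresholds."""
        return int(self.grid.size)

    @property
    def p(self) -> int:
        """Number of participants."""
        return len(self.participant_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: threshold, participant, serialized sequence."""
        rows = [
            {
                "threshold_dva_s": float(self.grid[i]),
                "participant_id": pid,
                "sequence": self.sequences[i][j].serialize(),
            }
            for i in range(self.t)
            for j, pid in enumerate(self.participant_ids)
        ]
        return pd.DataFrame(rows, columns=["threshold_dva_s", "participant_id", "sequence"])


@dataclass(frozen=True)
class SimilarityTrend:
    """Per-threshold mean similarity, tagged by comparison kind."""

    grid: np.ndarray
    values: np.ndarray
    kind: str  # "between" | "within" | "ideal"
    per_participant: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.grid.shape != self.values.shape:
            raise ValidationError("trend values must align with the grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError("trend values must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.grid, name=self.kind)


@dataclass(frozen=True)
class RangeSelection:
    """An accurate-threshold range and its argmax threshold."""

    lower: float
    upper: float
    argmax_threshold: float
    max_similarity: float
    delta: float
    floor: float

    def __post_init__(self) -> None:
        if not self.lower <= self.argmax_threshold <= self.upper:
            raise ValidationError("range must contain its argmax threshold")

    def contains(self, threshold: float) -> bool:
        return self.lower <= threshold <= self.upper


def threshold_sweep(
    recs: Sequence[GazeRecording],
    grid: np.ndarray | None = None,
    min_fix_ms: float = DEFAULT_MIN_FIX_MS,
    radius: float = DEFAULT_AOI_RADIUS,
    temporal_mode: str = "overlap",
) -> SweepResult:
    """Run detection + AOI mapping for every (threshold, participant).

    Velocities are computed once per recording and re-classified at each
    threshold.  Recordings are expected to be pre-filtered for missing
    data and must carry a target schedule.
    """
    grid = _check_grid(default_grid() if grid is None else grid)
    if not recs:
        raise DomainError("threshold_sweep requires at least one recording")
    per_thr: list[list[ScanPathSequence]] = [[] for _ in range(grid.size)]
    for j, rec in enumerate(recs):
        if not rec.targets:
            raise ValidationError(
                f"recording {rec.participant_id!r} carries no target schedule"
            )
        aois = build_aois(rec.targets, radius=radius)
        trace = compute_velocities(rec)
        for i, thr in enumerate(grid):
            try:
                fixations, _ = detect_fixations(
                    rec, float(thr), min_fix_ms, trace=trace
                )
                per_thr[i].append(map_fixations(fixations, aois, temporal_mode))
            except Exception as exc:  # annotate with sweep coordinates
                raise type(exc)(
                    f"threshold {thr} (i={i}), participant "
                    f"{rec.participant_id!r} (j={j}): {exc}"
                ) from exc
        logger.info(
            "swept participant %s (%d/%d) over %d thresholds",
            rec.participant_id, j + 1, len(recs), grid.size,
        )
    return SweepResult(
        grid=grid,
        participant_ids=tuple(rec.participant_id for rec in recs),
        sequences=tuple(tuple(row) for row in per_thr),
    )


def between_trend(
    sweep: SweepResult,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> SimilarityTrend:
    """Mean similarity over all unordered participant pairs per threshold.

    ``max_pairs`` optionally subsamples the pair set (seeded) for very
    large cohorts; the default is exhaustive enumeration.
    """
    if sweep.p < 2:
        raise DomainError(
            "between-participant comparisons need at least 2 participants"
        )
    pairs = list(itertools.combinations(range(sweep.p), 2))
    if max_pairs is not None and max_pairs < len(pairs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[int(i)] for i in np.sort(idx)]
    values = np.empty(sweep.t)
    for i in range(sweep.t):
        row = sweep.sequences[i]
        values[i] = float(np.mean([_sim_quiet(row[j], row[k]) for j, k in pairs]))
    return SimilarityTrend(grid=sweep.grid, values=values, kind="between")


def within_trend(sweep: SweepResult) -> SimilarityTrend:
    """Average similarity of each threshold's sequence to all others.

    For participant j, v_ij averages S(f_i, f_l) over the t-1 thresholds
    l != i; the trend is the participant mean vbar_i.  The full v_ij
    matrix (t x p) is kept on the result.
    """
    if sweep.t < 2:
        raise DomainError("within-participant comparisons need at least 2 thresholds")
    t, p = sweep.t, sweep.p
    v = np.zeros((t, p))
    for j in range(p):
        seqs = [sweep.sequences[i][j] for i in range(t)]
        # Pairwise similarity matrix over thresholds (symmetric).
        sim = np.ones((t, t))
        for a in range(t):
            for b in range(a + 1, t):
                sim[a, b] = sim[b, a] = _sim_quiet(seqs[a], seqs[b])
        v[:, j] = (sim.sum(axis=1) - 1.0) / (t - 1)  # drop self-similarity
    return SimilarityTrend(
        grid=sweep.grid, values=v.mean(axis=1), kind="within", per_participant=v
    )


def ideal_trend(sweep: SweepResult, ideal: ScanPathSequence) -> SimilarityTrend:
    """Per-threshold mean similarity to the ideal scan-path sequence."""
    if len(ideal) == 0:
        raise DomainError("ideal sequence must be nonempty")
    values = np.array(
        [
            np.mean([_sim_quiet(seq, ideal) for seq in sweep.sequences[i]])
            for i in range(sweep.t)
        ]
    )
    return SimilarityTrend(grid=sweep.grid, values=values, kind="ideal")


def _sim_quiet(a, b) -> float:
    """similarity() without the both-empty warning (legal in sweeps)."""
    if len(a) == 0 and len(b) == 0:
        return 1.0
    from .similarity import similarity

    return similarity(a, b)


def select_range(
    trend: SimilarityTrend,
    delta: float = DEFAULT_DELTA,
    floor: float = 0.0,
) -> RangeSelection:
    """Explicit plateau rule standing in for by-eye range identification.

    The argmax threshold is the grid point with the maximal trend value
    (ties broken toward the lowest threshold); the range is the maximal
    contiguous run of grid points containing the argmax whose values stay
    within ``delta`` of the maximum and at or above ``floor``.
    """
    values = trend.values
    if values.size == 0 or not np.any(np.isfinite(values)):
        raise DomainError("cannot select a range from an empty trend")
    imax = int(np.nanargmax(values))  # first occurrence = lowest threshold
    vmax = float(values[imax])
    ok = (values >= vmax - delta) & (values >= floor)
    lo = imax
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = imax
    while hi < values.size - 1 and ok[hi + 1]:
        hi += 1
    return RangeSelection(
        lower=float(trend.grid[lo]),
        upper=float(trend.grid[hi]),
        argmax_threshold=float(trend.grid[imax]),
        max_similarity=vmax,
        delta=delta,
        floor=floor,
    )


def trend_correlation(
    a: SimilarityTrend, b: SimilarityTrend
) -> tuple[float, float]:
    """Spearman rank correlation between two trends on the same grid.

    Average ranks handle ties; the two-sided p-value uses the standard
    large-sample t approximation.  A zero-variance trend has no defined
    rank correlation: (nan, nan) is returned rather than a number.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise DomainError("trends must share the same threshold grid")
    if a.grid.size < 3:
        raise DomainError("rank correlation needs at least 3 thresholds")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(a.values, b.values)
    return float(rho), float(p)


def benchmark_compare(
    trend_ideal: SimilarityTrend,
    candidate_thresholds: Iterable[float],
    benchmark: float = DEFAULT_BENCHMARK,
) -> pd.DataFrame:
    """Ideal-trend accuracy of candidate thresholds vs a benchmark.

    Each row reports a threshold's ideal-trend similarity and its
    difference from the benchmark threshold's value.  All thresholds must
    lie on the trend's grid.
    """
    def lookup(thr: float) -> float:
        hits = np.flatnonzero(np.isclose(trend_ideal.grid, thr))
        if hits.size == 0:
            raise DomainError(f"threshold {thr} is not on the sweep grid")
        return float(trend_ideal.values[int(hits[0])])

    bench_val = lookup(benchmark)
    rows = [
        {
            "threshold_dva_s": float(benchmark),
            "role": "benchmark",
            "ideal_similarity": bench_val,
            "difference_vs_benchmark": 0.0,
        }
    ]
    for thr in candidate_thresholds:
        val = lookup(float(thr))
        rows.append(
            {
                "threshold_dva_s": float(thr),
                "role": "candidate",
                "ideal_similarity": val,
                "difference_vs_benchmark": val - bench_val,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold_dva_s",
            "role",
            "ideal_similarity",
            "difference_vs_benchmark",
        ],
    )
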
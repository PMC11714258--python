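"""Model/Results interface tying the threshold-selection pipeline together.

``ThresholdSelectionModel`` is constructed from a cohort of gaze
recordings (applying the missing-data participant filter up front) and
``fit()`` runs the full analysis — threshold sweep, between/within/ideal
similarity trends, plateau-based range selection, Spearman trend
agreement, and the benchmark comparison — returning a
``ThresholdSelectionResults`` object with a ``summary()`` table and
plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .event_detection import DEFAULT_MIN_FIX_MS
from .gaze_io import GazeRecording, filter_participants, read_gaze_recording
from .scanpath import DEFAULT_AOI_RADIUS, ScanPathSequence, build_aois, ideal_sequence
from .threshold_selection import (
    DEFAULT_BENCHMARK,
    DEFAULT_DELTA,
    RangeSelection,
    SimilarityTrend,
    SweepResult,
    benchmark_compare,
    between_trend,
    default_grid,
    ideal_trend,
    select_range,
    threshold_sweep,
    trend_correlation,
    within_trend,
)

__all__ = ["ThresholdSelectionModel", "ThresholdSelectionResults"]


class ThresholdSelectionModel:
    """Gaze-velocity threshold selection for the I-VT algorithm.

    Parameters
    ----------
    recordings
        Cohort of :class:`GazeRecording` objects, each carrying its
        target schedule.  Recordings with more than ``max_missing``
        missing samples are excluded (the report is kept on the model).
    grid
        Velocity thresholds to sweep (default 10-400 deg/s, step 10).
    min_fix_ms, aoi_radius, temporal_mode
        I-VT and AOI-mapping parameters.
    ideal
        The ideal scan-path sequence.  When omitted it is derived from
        the first retained recording's target schedule (targets in order
        of appearance), which is the correct ideal for a task whose
        token alphabet indexes targets by order.
    """

    def __init__(
        self,
        recordings: Sequence[GazeRecording],
        grid: np.ndarray | None = None,
        min_fix_ms: float = DEFAULT_MIN_FIX_MS,
        aoi_radius: float = DEFAULT_AOI_RADIUS,
        temporal_mode: str = "overlap",
        ideal: ScanPathSequence | None = None,
        max_missing: float = 0.10,
    ) -> None:
        retained, report = filter_participants(recordings, max_missing)
        if not retained:
            raise DomainError("no recordings survive the missing-data filter")
        self.recordings = retained
        self.exclusion_report = report
        self.grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
        self.min_fix_ms = float(min_fix_ms)
        self.aoi_radius = float(aoi_radius)
        self.temporal_mode = temporal_mode
        if ideal is None and retained[0].targets:
            ideal = ideal_sequence(build_aois(retained[0].targets, aoi_radius))
        self.ideal = ideal

    @classmethod
    def from_files(
        cls,
        paths: Iterable[str | Path],
        dialect=None,
        **kwargs,
    ) -> "ThresholdSelectionModel":
        """Build a model from per-participant sample CSVs on disk."""
        recs = [read_gaze_recording(p, dialect=dialect) for p in paths]
        return cls(recs, **kwargs)

    def fit(
        self,
        delta: float = DEFAULT_DELTA,
        floor: float = 0.0,
        benchmark: float = DEFAULT_BENCHMARK,
        max_pairs: int | None = None,
        seed: int | None = None,
    ) -> "ThresholdSelectionResults":
        """Run the sweep and derive trends, ranges and agreement measures."""
        sweep = threshold_sweep(
            self.recordings,
            self.grid,
            min_fix_ms=self.min_fix_ms,
            radius=self.aoi_radius,
            temporal_mode=self.temporal_mode,
        )
        trends: dict[str, SimilarityTrend] = {}
        if sweep.p >= 2:
            trends["between"] = between_trend(sweep, max_pairs=max_pairs, seed=seed)
        if sweep.t >= 2:
            trends["within"] = within_trend(sweep)
        if self.ideal is not None and len(self.ideal):
            trends["ideal"] = ideal_trend(sweep, self.ideal)

        ranges = {
            kind: select_range(tr, delta=delta, floor=floor)
            for kind, tr in trends.items()
        }
        correlations: dict[tuple[str, str], tuple[float, float]] = {}
        if sweep.t >= 3:  # rank correlation is undefined on shorter grids
            names = list(trends)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    correlations[(a, b)] = trend_correlation(trends[a], trends[b])

        bench_report = None
        if "ideal" in trends:
            candidates = [
                ranges[k].argmax_threshold for k in ("between", "within") if k in ranges
            ]
            if np.any(np.isclose(self.grid, benchmark)):
                bench_report = benchmark_compare(
                    trends["ideal"], candidates, benchmark=benchmark
                )
        return ThresholdSelectionResults(
            model=self,
            sweep=sweep,
            trends=trends,
            ranges=ranges,
            correlations=correlations,
            benchmark=benchmark,
            benchmark_report=bench_report,
            delta=delta,
            floor=floor,
        )


@dataclass
class ThresholdSelectionResults:
    """Fitted trends, selected ranges and diagnostics of a cohort sweep."""

    model: ThresholdSelectionModel
    sweep: SweepResult
    trends: dict[str, SimilarityTrend]
    ranges: dict[str, RangeSelection]
    correlations: dict[tuple[str, str], tuple[float, float]]
    benchmark: float
    benchmark_report: pd.DataFrame | None
    delta: float
    floor: float

    # -- tabular views ----------------------------------------------------
    def trends_frame(self) -> pd.DataFrame:
        """Wide table: one row per threshold, one column per trend kind."""
        data = {"threshold_dva_s": self.sweep.grid}
        for kind, tr in self.trends.items():
            data[kind] = tr.values
        return pd.DataFrame(data)

    def ranges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trend": kind,
                "lower_dva_s": sel.lower,
                "upper_dva_s": sel.upper,
                "argmax_dva_s": sel.argmax_threshold,
                "max_similarity": sel.max_similarity,
                "delta": sel.delta,
                "floor": sel.floor,
            }
            for kind, sel in self.ranges.items()
        ]
        return pd.DataFrame(rows)

    def correlations_frame(self) -> pd.DataFrame:
        rows = [
            {"trend_a": a, "trend_b": b, "spearman_rho": rho, "p_value": p}
            for (a, b), (rho, p) in self.correlations.items()
        ]
        return pd.DataFrame(rows, columns=["trend_a", "trend_b", "spearman_rho", "p_value"])

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted analysis."""
        g = self.sweep.grid
        lines = [
            "        Gaze-Velocity Threshold Selection (I-VT)",
            "=" * 58,
            f"participants: {self.sweep.p:<6d} thresholds: {self.sweep.t} "
            f"({g[0]:g}-{g[-1]:g} deg/s)",
            f"min fixation: {self.model.min_fix_ms:g} ms    AOI radius: "
            f"{self.model.aoi_radius:g} dva    plateau delta: {self.delta:g}",
            "-" * 58,
            f"{'trend':<10}{'argmax':>8}{'max sim':>10}{'range (deg/s)':>18}",
        ]
        for kind in ("between", "within", "ideal"):
            if kind not in self.ranges:
                continue
            sel = self.ranges[kind]
            lines.append(
                f"{kind:<10}{sel.argmax_threshold:>8g}{sel.max_similarity:>10.3f}"
                f"{f'{sel.lower:g}-{sel.upper:g}':>18}"
            )
        if self.correlations:
            lines.append("-" * 58)
            for (a, b), (rho, p) in self.correlations.items():
                lines.append(
                    f"Spearman rho({a}, {b}) = {rho:.3f}  (p = {p:.2g})"
                )
        if self.benchmark_report is not None:
            lines.append("-" * 58)
            rep = self.benchmark_report
            bench = rep[rep.role == "benchmark"].iloc[0]
            lines.append(
                f"benchmark {bench.threshold_dva_s:g} deg/s ideal similarity: "
                f"{bench.ideal_similarity:.3f}"
            )
            lookup = dict(zip(rep.threshold_dva_s, rep.ideal_similarity))
            for kind in ("between", "within"):
                sel = self.ranges.get(kind)
                if sel is None or sel.argmax_threshold not in lookup:
                    continue
                val = lookup[sel.argmax_threshold]
                lines.append(
                    f"  {kind} argmax {sel.argmax_threshold:g} deg/s: "
                    f"{val:.3f} ({val - bench.ideal_similarity:+.3f} vs benchmark)"
                )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Trend lines with shaded accurate ranges (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        colors = {"between": "tab:red", "within": "tab:blue", "ideal": "black"}
        for kind, tr in self.trends.items():
            ax.plot(tr.grid, tr.values, label=kind, color=colors.get(kind))
            sel = self.ranges.get(kind)
            if sel is not None:
                ax.axvspan(sel.lower, sel.upper, color=colors.get(kind), alpha=0.08)
                ax.plot(
                    [sel.argmax_threshold],
                    [sel.max_similarity],
                    "o",
                    color=colors.get(kind),
                )
        ax.set_xlabel("gaze velocity threshold (deg/s)")
        ax.set_ylabel("string-edit similarity")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        """Write trends / ranges / correlations (+ benchmark) CSVs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("trends.csv", self.trends_frame()),
            ("ranges.csv", self.ranges_frame()),
            ("correlations.csv", self.correlations_frame()),
            ("exclusions.csv", self.model.exclusion_report),
        ):
            path = out_dir / name
            frame.to_csv(path, index=False)
            written.append(path)
        if self.benchmark_report is not None:
            path = out_dir / "benchmark.csv"
            self.benchmark_report.to_csv(path, index=False)
            written.append(path)
        return written
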
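"""Reading, validating and filtering raw gaze recordings.

A recording is a time-ordered monocular gaze stream in degrees of visual
angle (dva) together with the schedule of bullseye targets that defines the
random-saccade task.  The on-disk dialect is a per-sample CSV with columns
``t_ms,x_dva,y_dva`` (missing samples encoded as empty cells or NaN) and a
companion ``*_targets.csv`` with columns
``label,x_dva,y_dva,onset_ms,offset_ms``.

Missing samples are never interpolated: they are carried as ``valid=False``
and excluded from every velocity and centroid computation downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

__all__ = [
    "TargetEvent",
    "GazeRecording",
    "DEFAULT_DIALECT",
    "read_gaze_recording",
    "write_recording",
    "missing_fraction",
    "filter_participants",
]

#: Default column-name mapping of the on-disk dialect.
DEFAULT_DIALECT: Mapping[str, str] = {"t": "t_ms", "x": "x_dva", "y": "y_dva"}

_TARGET_COLUMNS = ["label", "x_dva", "y_dva", "onset_ms", "offset_ms"]


@dataclass(frozen=True)
class TargetEvent:
    """A bullseye target shown at a fixed position for a visibility window.

    Labels are two-character zero-padded tokens ("00".."99") assigned in
    order of appearance; the token alphabet of every downstream scan-path
    sequence is exactly the set of target labels.
    """

    label: str
    x: float
    y: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (isinstance(self.label, str) and len(self.label) == 2):
            raise ValidationError(
                f"target label must be a two-character token, got {self.label!r}"
            )
        if not self.offset > self.onset:
            raise ValidationError(
                f"target {self.label!r}: offset ({self.offset}) must exceed "
                f"onset ({self.onset})"
            )


class GazeRecording:
    """A participant's gaze samples plus the target schedule.

    Parameters
    ----------
    participant_id
        Opaque identifier (usually the file stem).
    t
        Sample timestamps in milliseconds, strictly increasing, >= 0.
    x, y
        Gaze position in dva.  Non-finite entries mark missing samples.
    targets
        Ordered, non-overlapping :class:`TargetEvent` objects.
    sampling_rate
        Nominal rate in Hz; inferred from the median timestamp step when
        omitted.
    """

    def __init__(
        self,
        participant_id: str,
        t: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        targets: Sequence[TargetEvent] = (),
        sampling_rate: float | None = None,
        valid: np.ndarray | None = None,
    ) -> None:
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValidationError("t, x, y must be 1-D arrays of equal length")
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise ValidationError("timestamps must be finite and non-negative")
        if t.size > 1:
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                raise ValidationError(
                    f"timestamps must strictly increase; first violation at "
                    f"row {int(bad[0]) + 1}"
                )
        if valid is None:
            valid = np.isfinite(x) & np.isfinite(y)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != t.shape:
                raise ValidationError("valid mask must match sample count")
            valid = valid & np.isfinite(x) & np.isfinite(y)
        if sampling_rate is None:
            if t.size > 1:
                sampling_rate = 1000.0 / float(np.median(np.diff(t)))
            else:
                sampling_rate = 1000.0
        if not sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        targets = tuple(targets)
        _check_targets(targets)
        self.participant_id = str(participant_id)
        self.t = t
        self.x = x
        self.y = y
        self.valid = valid
        self.targets = targets
        self.sampling_rate = float(sampling_rate)

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def samples(self) -> pd.DataFrame:
        """Samples as a DataFrame in the on-disk dialect column order."""
        return pd.DataFrame(
            {"t_ms": self.t, "x_dva": self.x, "y_dva": self.y, "valid": self.valid}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GazeRecording {self.participant_id!r}: {self.n_samples} samples, "
            f"{len(self.targets)} targets, {self.sampling_rate:g} Hz>"
        )


def _check_targets(targets: Sequence[TargetEvent]) -> None:
    labels = [tgt.label for tgt in targets]
    if len(set(labels)) != len(labels):
        raise ValidationError("target labels must be unique")
    for prev, nxt in zip(targets, targets[1:]):
        if nxt.onset < prev.offset:
            raise ValidationError(
                f"targets {prev.label!r} and {nxt.label!r} overlap in time"
            )
        if nxt.onset < prev.onset:
            raise ValidationError("targets must be ordered by onset")


def read_gaze_recording(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    targets_path: str | Path | None = None,
    participant_id: str | None = None,
    sampling_rate: float | None = None,
) -> GazeRecording:
    """Read a per-sample CSV (plus companion target schedule) from disk.

    Rows whose x or y is empty or non-finite become samples with
    ``valid=False``.  The companion schedule defaults to
    ``<stem>_targets.csv`` next to the sample file and may be absent (the
    recording then carries no targets).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    table = pd.read_csv(path, float_precision="round_trip")
    for key in ("t", "x", "y"):
        col = dialect.get(key, DEFAULT_DIALECT[key])
        if col not in table.columns:
            raise FormatError(
                f"{path.name}: required column {col!r} (for {key!r}) not found"
            )
    t = table[dialect.get("t", "t_ms")].to_numpy(dtype=float)
    x = table[dialect.get("x", "x_dva")].to_numpy(dtype=float)
    y = table[dialect.get("y", "y_dva")].to_numpy(dtype=float)

    if targets_path is None:
        candidate = path.with_name(path.stem + "_targets.csv")
        targets_path = candidate if candidate.exists() else None
    targets: tuple[TargetEvent, ...] = ()
    if targets_path is not None:
        targets = tuple(read_target_schedule(targets_path))

    pid = participant_id if participant_id is not None else path.stem
    return GazeRecording(pid, t, x, y, targets, sampling_rate=sampling_rate)


def read_target_schedule(path: str | Path) -> list[TargetEvent]:
    """Read a ``label,x_dva,y_dva,onset_ms,offset_ms`` schedule file."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    for col in _TARGET_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path.name}: required column {col!r} not found")
    return [
        TargetEvent(
            label=str(row.label).zfill(2),
            x=float(row.x_dva),
            y=float(row.y_dva),
            onset=float(row.onset_ms),
            offset=float(row.offset_ms),
        )
        for row in table.itertuples()
    ]


def write_recording(rec: GazeRecording, path: str | Path) -> Path:
    """Write a recording (and its schedule, if any) in the package dialect.

    Returns the sample-file path; the schedule goes to
    ``<stem>_targets.csv`` alongside it.
    """
    path = Path(path)
    frame = pd.DataFrame({"t_ms": rec.t, "x_dva": rec.x, "y_dva": rec.y})
    frame.loc[~rec.valid, ["x_dva", "y_dva"]] = np.nan
    # %.17g round-trips IEEE doubles exactly.
    frame.to_csv(path, index=False, float_format="%.17g")
    if rec.targets:
        sched = pd.DataFrame(
            {
                "label": [tg.label for tg in rec.targets],
                "x_dva": [tg.x for tg in rec.targets],
                "y_dva": [tg.y for tg in rec.targets],
                "onset_ms": [tg.onset for tg in rec.targets],
                "offset_ms": [tg.offset for tg in rec.targets],
            }
        )
        sched.to_csv(
            path.with_name(path.stem + "_targets.csv"),
            index=False,
            float_format="%.17g",
        )
    return path


def missing_fraction(rec: GazeRecording) -> float:
    """Fraction of samples flagged missing (blinks, occlusions).

    Raises :class:`DomainError` on an empty recording.
    """
    if rec.n_samples == 0:
        raise DomainError("missing_fraction is undefined for an empty recording")
    return float(np.count_nonzero(~rec.valid)) / rec.n_samples


def filter_participants(
    recs: Iterable[GazeRecording], max_missing: float = 0.10
) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Drop recordings with *strictly more than* ``max_missing`` missing.

    Returns the retained recordings (input order preserved) and an exclusion
    report with one row per input recording
    (``participant_id,missing_fraction,excluded``).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise DomainError("max_missing must lie in [0, 1]")
    retained: list[GazeRecording] = []
    rows = []
    for rec in recs:
        frac = missing_fraction(rec)
        excluded = frac > max_missing
        if not excluded:
            retained.append(rec)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "missing_fraction": frac,
                "excluded": excluded,
            }
        )
    report = pd.DataFrame(rows, columns=["participant_id", "missing_fraction", "excluded"])
    return retained, report


def parse_participant_id(path: str | Path) -> str:
    """Participant id from a sample-file path (strips a trailing _targets)."""
    stem = Path(path).stem
    return re.sub(r"_targets$", "", stem)
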
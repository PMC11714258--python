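"""AOI construction and fixation-to-token mapping.

Each bullseye target defines one circular, time-windowed area of interest
(AOI) labelled with a two-character token.  A fixation contributes its
AOI's token when it overlaps the AOI's visibility window temporally and
its centroid lies within the AOI radius spatially (closed disc).
Consecutive repeats of the same token are preserved — a split fixation on
one target legitimately yields the token twice — and edit operations
downstream act on whole tokens, never on their constituent characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .event_detection import Fixation
from .gaze_io import TargetEvent

__all__ = [
    "AOI",
    "ScanPathSequence",
    "DEFAULT_AOI_RADIUS",
    "build_aois",
    "map_fixations",
    "ideal_sequence",
]

#: Default AOI radius in dva (sized to typical tracker validation error).
DEFAULT_AOI_RADIUS: float = 2.0


@dataclass(frozen=True)
class AOI:
    """A circular, time-windowed area of interest with a token label."""

    label: str
    center_x: float
    center_y: float
    radius: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"AOI {self.label!r}: radius must be positive")
        if not self.offset > self.onset:
            raise ValidationError(f"AOI {self.label!r}: offset must exceed onset")


@dataclass(frozen=True)
class ScanPathSequence:
    """An ordered token sequence; the unit compared by edit similarity."""

    tokens: tuple[str, ...]

    def __init__(self, tokens: Iterable[str] = ()) -> None:
        object.__setattr__(self, "tokens", tuple(str(tok) for tok in tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def serialize(self) -> str:
        """Comma-joined token line (``00,01,01,04,...``)."""
        return ",".join(self.tokens)

    @classmethod
    def parse(cls, line: str) -> "ScanPathSequence":
        line = line.strip()
        return cls(line.split(",")) if line else cls(())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScanPathSequence({self.serialize()!r})"


def build_aois(
    targets: Sequence[TargetEvent], radius: float = DEFAULT_AOI_RADIUS
) -> list[AOI]:
    """One AOI per target event, inheriting label, window and centre."""
    labels = [tgt.label for tgt in targets]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate AOI labels in target schedule")
    return [
        AOI(
            label=tgt.label,
            center_x=tgt.x,
            center_y=tgt.y,
            radius=radius,
            onset=tgt.onset,
            offset=tgt.offset,
        )
        for tgt in targets
    ]


def map_fixations(
    fixations: Sequence[Fixation],
    aois: Sequence[AOI],
    temporal_mode: str = "overlap",
) -> ScanPathSequence:
    """Map fixations onto AOIs and emit the scan-path token sequence.

    A fixation matches an AOI when its interval overlaps the AOI's
    visibility window (``temporal_mode="overlap"``, any nonzero overlap;
    ``"onset"`` requires the fixation onset to fall inside the window) and
    its centroid lies within the AOI radius of the centre (closed disc).
    Each fixation emits at most one token; when a fixation matches two
    AOIs it is assigned the one with the larger temporal overlap, ties
    going to the earlier AOI.  Fixations matching no AOI emit nothing.
    """
    if temporal_mode not in ("overlap", "onset"):
        raise ValidationError(f"unknown temporal_mode {temporal_mode!r}")
    if not fixations or not aois:
        return ScanPathSequence(())

    a_on = np.array([a.onset for a in aois])
    a_off = np.array([a.offset for a in aois])
    ax = np.array([a.center_x for a in aois])
    ay = np.array([a.center_y for a in aois])
    radius = np.array([a.radius for a in aois])
    order = np.argsort(a_on, kind="stable")  # tie-break: earlier AOI wins

    f_on = np.array([f.onset for f in fixations])
    f_off = np.array([f.offset for f in fixations])
    cx = np.array([f.centroid_x for f in fixations])
    cy = np.array([f.centroid_y for f in fixations])

    overlap = np.minimum(f_off[:, None], a_off[None, :]) - np.maximum(
        f_on[:, None], a_on[None, :]
    )
    if temporal_mode == "overlap":
        temporal = overlap > 0
    else:
        temporal = (f_on[:, None] >= a_on[None, :]) & (f_on[:, None] < a_off[None, :])
    spatial = np.hypot(cx[:, None] - ax[None, :], cy[:, None] - ay[None, :]) <= radius
    eligible = temporal & spatial

    tokens: list[str] = []
    labels = [aois[k].label for k in order]
    score = np.where(eligible, overlap, -np.inf)[:, order]
    best = np.argmax(score, axis=1)  # first (earliest-onset) max wins ties
    has_match = eligible.any(axis=1)
    for i in np.flatnonzero(has_match):
        tokens.append(labels[int(best[i])])
    return ScanPathSequence(tokens)


def ideal_sequence(aois: Sequence[AOI]) -> ScanPathSequence:
    """The token order a perfectly compliant observer would produce."""
    ordered = sorted(aois, key=lambda a: a.onset)
    return ScanPathSequence(a.label for a in ordered)
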
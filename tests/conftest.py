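"""Shared fixtures: hand-built recordings and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from scanpathselect import GazeRecording, SimulationParams, TargetEvent, generate_cohort


@pytest.fixture
def make_recording():
    """Factory for recordings from raw arrays (1000 Hz unless t given)."""

    def _make(x, y, t=None, targets=(), participant_id="P0"):
        x = np.asarray(x, dtype=float)
        if t is None:
            t = np.arange(x.size, dtype=float)
        return GazeRecording(
            participant_id, t, x, np.asarray(y, dtype=float), targets=targets
        )

    return _make


@pytest.fixture
def step_recording(make_recording):
    """Two 1 s dwells at (0,0) and (10,0) joined by a 40 ms saccade.

    Clean signal (no jitter), 1000 Hz; the saccade moves linearly, so its
    speed is 10 dva / 0.04 s = 250 dva/s on every pair.
    """
    n_dwell, n_sacc = 1000, 40
    x = np.concatenate(
        [
            np.zeros(n_dwell),
            np.linspace(0, 10, n_sacc + 2)[1:-1],
            np.full(n_dwell, 10.0),
        ]
    )
    y = np.zeros_like(x)
    targets = (
        TargetEvent("00", 0.0, 0.0, 0.0, 1020.0),
        TargetEvent("01", 10.0, 0.0, 1020.0, 2040.0),
    )
    return make_recording(x, y, targets=targets)


@pytest.fixture(scope="session")
def small_cohort():
    """5 quick simulated participants, 10 targets each (default noise)."""
    params = SimulationParams(n_targets=10, seed=42)
    return generate_cohort(5, params)
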
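"""Shared fixtures: synthetic trials reused across test modules.

Heavy simulated trials are session-scoped so the cost of rendering and
smoothing them is paid once.
"""
from __future__ import annotations

import numpy as np
import pytest

import bowerkit as bk


def make_series(grids, timestamps, lights_on=None, footprint=0.01):
    """Build a DepthSeries from plain arrays (distances in mm)."""
    frames = [bk.DepthFrame(np.asarray(g, dtype=float), float(t))
              for g, t in zip(grids, timestamps)]
    return bk.DepthSeries(frames, lights_on or [],
                          bk.GridCalibration(footprint))


@pytest.fixture(scope="session")
def pit_trial():
    """A 5-day pit trial with construction on every day (50 lights-on
    hourly bins), default noise and dropout.

    Events carry a full-scale 1.5 cm^3 mouthful at a correspondingly
    lower rate, the configuration used for volume-recovery checks.
    """
    spec = bk.TrialSpec(species_policy="pit", days=5, build_day_prob=1.0,
                        per_event_volume_cm3=1.5, pairs_per_burst=6.0,
                        seed=11)
    return bk.simulate_trial(spec)


@pytest.fixture(scope="session")
def pit_processed(pit_trial):
    """The pit trial after island interpolation and SG smoothing."""
    return bk.process_series(pit_trial.series)


@pytest.fixture(scope="session")
def small_trial():
    """A cheap 1-day control-policy trial on a reduced grid."""
    spec = bk.TrialSpec(species_policy="control", days=1,
                        grid_shape=(60, 80), frames_per_window=4,
                        feed_events_per_day=40.0, misc_events_per_day=10.0,
                        seed=7)
    return bk.simulate_trial(spec)
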
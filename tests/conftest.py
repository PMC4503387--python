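"""Shared fixtures and independent oracles for the mpquant test suite."""

import math

import numpy as np
import pytest

from mpquant import contraction as ct
from mpquant import synthetic as syn


def brute_force_msd(positions, dt, max_lag_fraction=1 / 3):
    """All-pairs enumeration oracle for the overlapping MSD estimator."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    n_steps = n - 1
    kmax = max(1, min(int(math.floor(max_lag_fraction * n_steps + 1e-9)), n_steps))
    lags, msd, n_pairs = [], [], []
    for k in range(1, kmax + 1):
        vals = []
        for i in range(n - k):
            dx = positions[i + k, 0] - positions[i, 0]
            dy = positions[i + k, 1] - positions[i, 1]
            vals.append(dx * dx + dy * dy)
        lags.append(k * dt)
        msd.append(sum(vals) / len(vals))
        n_pairs.append(len(vals))
    return np.array(lags), np.array(msd), np.array(n_pairs)


def random_track_positions(rng, n):
    """A random (correlated) walk used as generic MSD-oracle input."""
    steps = rng.normal(0.0, rng.uniform(0.5, 5.0), size=(n - 1, 2))
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


@pytest.fixture(scope="session")
def beat_1hz_analysis():
    """One full-length 1-Hz beating stack analysed end to end (shared)."""
    cfg = syn.SyntheticBeatConfig(beat_frequency=1.0, peak_velocity=10.0, seed=301)
    result = syn.simulate_beating_stack(cfg)
    field = ct.block_match_motion(result.stack, block_size=16, search_radius=4, step=8)
    waveform = ct.detect_beats(ct.motion_waveform(field))
    return result, field, waveform
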
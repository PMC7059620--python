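"""Shared fixtures and independent oracles.

The oracles here deliberately use different algorithms from the package:
the correlogram oracle enumerates all spike pairs in O(n^2), and the
SPIKE-distance oracle evaluates the dissimilarity profile pointwise on a
dense time grid and trapezoid-averages it, rather than integrating the
piecewise-linear profile exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from surfspike.types import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_correlogram(tx, ty, bin_ms=5.0, max_lag_ms=100.0):
    """O(n^2) pair enumeration over half-open lag bins [edge, edge + bin)."""
    n_bins = int(round(2 * max_lag_ms / bin_ms))
    counts = np.zeros(n_bins, dtype=np.int64)
    for a in tx:
        for b in ty:
            d_ms = (b - a) * 1000.0
            if -max_lag_ms <= d_ms < max_lag_ms:
                counts[int(np.floor((d_ms + max_lag_ms) / bin_ms))] += 1
    return counts


def spike_distance_grid_oracle(tx, ty, t0, t1, dt=1e-4):
    """Pointwise SPIKE-distance profile on a dense grid, trapezoid-averaged.

    Auxiliary spikes at the interval edges, matching the edge convention of
    the implementation under test.
    """
    tx = np.asarray(tx, dtype=float)
    ty = np.asarray(ty, dtype=float)
    ax = np.unique(np.concatenate(([t0], tx[(tx >= t0) & (tx <= t1)], [t1])))
    ay = np.unique(np.concatenate(([t0], ty[(ty >= t0) & (ty <= t1)], [t1])))
    ts = np.arange(t0, t1 + dt / 2, dt)
    interior = ts < t1

    def terms(ts_in, aug, other):
        j = np.searchsorted(aug, ts_in, side="right")
        tp, tf = aug[j - 1], aug[j]

        def nearest(v):
            k = np.searchsorted(other, v)
            left = other[np.clip(k - 1, 0, other.size - 1)]
            right = other[np.clip(k, 0, other.size - 1)]
            return np.minimum(np.abs(v - left), np.abs(v - right))

        return tp, tf, nearest(tp), nearest(tf)

    s = np.zeros_like(ts)
    t_in = ts[interior]
    tpx, tfx, dpx, dfx = terms(t_in, ax, ay)
    tpy, tfy, dpy, dfy = terms(t_in, ay, ax)
    x1, x2 = tfx - tpx, tfy - tpy
    u1 = (dpx * (tfx - t_in) + dfx * (t_in - tpx)) / x1
    u2 = (dpy * (tfy - t_in) + dfy * (t_in - tpy)) / x2
    s[interior] = (u1 * x2 + u2 * x1) / (2.0 * (0.5 * (x1 + x2)) ** 2)
    return np.trapezoid(s, ts) / (t1 - t0)


def poisson_train(rate, duration, rng, unit_id="u", **kw):
    """Homogeneous Poisson spike train helper."""
    n = rng.poisson(rate * duration)
    return SpikeTrain(unit_id, np.unique(rng.uniform(0, duration, n)), **kw)
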
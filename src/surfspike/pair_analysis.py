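"""Surface-depth pair analysis.

For every (depth SUA, surface SUA) pair the pipeline computes a spike-time
cross-correlogram (5 ms bins over [-100, 100) ms, positive lags meaning the
surface unit fires after the depth unit), its peak lag, the SPIKE-distance
between the two trains, and the 3-D Euclidean distance between the contacts
that recorded them. Across pairs, a Pearson correlation of SPIKE-distance
against physical distance quantifies whether synchrony falls off with
separation.

SPIKE-distance is the standard parameter-free, time-resolved dissimilarity
between spike trains: at every time t each train contributes weighted differences
between its preceding/following spikes and the nearest spikes of the other
train, normalized by the local mean inter-spike interval; the profile S(t)
is averaged over the analysis interval. It is 0 for identical trains and
bounded by 1. Auxiliary spikes are placed at the interval edges so the
profile is defined everywhere. Between consecutive spikes (of either train)
the profile is linear in t, so the time average here is computed exactly by
trapezoidal integration over those segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ElectrodeGeometry, PairRecord, SpikeTrain

__all__ = [
    "Correlogram",
    "cross_correlogram",
    "correlogram_peak_lag",
    "spike_distance",
    "physical_distance",
    "pair_table",
]


@dataclass(frozen=True)
class Correlogram:
    """Spike-pair count histogram over signed lags (ms)."""

    lags: np.ndarray  # bin centres, ms
    counts: np.ndarray  # nonnegative integers
    bin_width: float = 5.0  # ms


def _restrict_to_periods(times: np.ndarray, periods) -> np.ndarray:
    if periods is None:
        return times
    keep = np.zeros(times.size, dtype=bool)
    for t0, t1 in periods:
        keep |= (times >= t0) & (times <= t1)
    return times[keep]


def cross_correlogram(x: SpikeTrain, y: SpikeTrain, bin: float = 5.0,
                      max_lag: float = 100.0, periods=None) -> Correlogram:
    """Count spike pairs by lag ``ty - tx`` in half-open bins.

    Parameters
    ----------
    x, y : SpikeTrain
        Reference (depth) and target (surface) trains.
    bin, max_lag : float
        Bin width and lag range in ms; lags cover ``[-max_lag, max_lag)``.
    periods : list of (t0, t1), optional
        Analysis periods (e.g. baseline only, or baseline plus stimulus);
        both spikes of a pair must fall inside the periods. None keeps all.
    """
    if bin <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(round(2 * max_lag / bin))
    edges = (-max_lag + bin * np.arange(n_bins + 1)) / 1000.0  # seconds
    tx = _restrict_to_periods(x.times, periods)
    ty = _restrict_to_periods(y.times, periods)
    counts = np.zeros(n_bins, dtype=np.int64)
    if tx.size and ty.size:
        lo = np.searchsorted(ty, tx + edges[0], side="left")
        hi = np.searchsorted(ty, tx + edges[-1], side="left")
        deltas = np.concatenate([ty[a:b] - t for t, a, b in zip(tx, lo, hi)]) \
            if np.any(hi > lo) else np.empty(0)
        if deltas.size:
            idx = np.floor((deltas - edges[0]) * 1000.0 / bin).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts, idx, 1)
    centers = (edges[:-1] + edges[1:]) / 2.0 * 1000.0
    return Correlogram(centers, counts, bin)


def correlogram_peak_lag(c: Correlogram) -> float:
    """Centre (ms) of the maximal-count bin.

    Ties are broken by smallest absolute lag, then negative before positive,
    so the result is deterministic. Raises on an all-zero correlogram.
    """
    if c.counts.max(initial=0) <= 0:
        raise ValueError("peak lag undefined for an all-zero correlogram")
    best = np.flatnonzero(c.counts == c.counts.max())
    order = sorted(best, key=lambda i: (abs(c.lags[i]), c.lags[i]))
    return float(c.lags[order[0]])


def _nearest_distance(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Distance from each value to the nearest element of sorted_ref."""
    j = np.searchsorted(sorted_ref, values)
    left = sorted_ref[np.clip(j - 1, 0, sorted_ref.size - 1)]
    right = sorted_ref[np.clip(j, 0, sorted_ref.size - 1)]
    return np.minimum(np.abs(values - left), np.abs(values - right))


def spike_distance(x: SpikeTrain, y: SpikeTrain, interval: tuple) -> float:
    """Time-averaged SPIKE-distance between two trains over ``interval``.

    Returns 0 for identical trains and values toward 1 for increasingly
    dyssynchronous trains. By edge convention, the distance is 0 when both
    trains are empty in the interval and 1 when exactly one is.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if not t1 > t0:
        raise ValueError("interval must have positive length")
    tx = x.times[(x.times >= t0) & (x.times <= t1)]
    ty = y.times[(y.times >= t0) & (y.times <= t1)]
    if tx.size == 0 and ty.size == 0:
        return 0.0
    if tx.size == 0 or ty.size == 0:
        return 1.0
    ax = np.unique(np.concatenate(([t0], tx, [t1])))
    ay = np.unique(np.concatenate(([t0], ty, [t1])))
    events = np.unique(np.concatenate((ax, ay)))
    a, b = events[:-1], events[1:]

    def segment_terms(aug):
        i_p = np.searchsorted(aug, a, side="right") - 1
        t_p = aug[i_p]
        t_f = aug[np.searchsorted(aug, a, side="right")]
        return t_p, t_f

    tpx, tfx = segment_terms(ax)
    tpy, tfy = segment_terms(ay)
    dpx = _nearest_distance(tpx, ay)
    dfx = _nearest_distance(tfx, ay)
    dpy = _nearest_distance(tpy, ax)
    dfy = _nearest_distance(tfy, ax)
    xisi1 = tfx - tpx
    xisi2 = tfy - tpy

    def profile_at(t):
        u1 = (dpx * (tfx - t) + dfx * (t - tpx)) / xisi1
        u2 = (dpy * (tfy - t) + dfy * (t - tpy)) / xisi2
        mean_isi = 0.5 * (xisi1 + xisi2)
        return (u1 * xisi2 + u2 * xisi1) / (2.0 * mean_isi**2)

    s_left = profile_at(a)
    s_right = profile_at(b)
    integral = np.sum((b - a) * 0.5 * (s_left + s_right))
    return float(integral / (t1 - t0))


def physical_distance(g: ElectrodeGeometry, e1: str, e2: str) -> float:
    """3-D Euclidean distance (um) between two contacts."""
    return float(np.linalg.norm(g.position(e1) - g.position(e2)))


def pair_table(trains: dict, geometry: ElectrodeGeometry, interval: tuple,
               periods=None, labels: str = "SUA"):
    """All depth-surface pair metrics plus the distance-synchrony correlation.

    Parameters
    ----------
    trains : dict
        unit_id -> SpikeTrain; only trains whose label matches ``labels`` and
        whose electrode is in the geometry are paired.
    interval : (t0, t1)
        Interval over which SPIKE-distance is averaged (baseline plus
        stimulus periods by default; pass baseline-only via ``periods`` for
        the correlograms and a matching ``interval``).
    periods : list of (t0, t1), optional
        Analysis periods for the correlograms (None keeps everything).

    Returns
    -------
    (DataFrame, r, p)
        One row per (depth SUA, surface SUA) pair with columns
        ``depth_unit, surface_unit, spike_distance, physical_distance,
        peak_lag``; Pearson r and p of spike vs physical distance across
        pairs, or ``(nan, nan)`` when fewer than 3 pairs exist or either
        column is constant.
    """
    probe_of = dict(zip(geometry.table.electrode_id.astype(str), geometry.table.probe))
    depth_units, surface_units = [], []
    for tr in trains.values():
        if tr.label != labels or tr.electrode_id is None or str(tr.electrode_id) not in probe_of:
            continue
        if probe_of[str(tr.electrode_id)] == "surface":
            surface_units.append(tr)
        else:
            depth_units.append(tr)
    records = []
    for d in depth_units:
        for s in surface_units:
            ccg = cross_correlogram(d, s, periods=periods)
            lag = correlogram_peak_lag(ccg) if ccg.counts.max(initial=0) > 0 else None
            records.append(PairRecord(
                depth_unit=d.unit_id, surface_unit=s.unit_id,
                spike_distance=spike_distance(d, s, interval),
                physical_distance=physical_distance(geometry, d.electrode_id, s.electrode_id),
                peak_lag=lag,
            ))
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["depth_unit", "surface_unit", "spike_distance",
                               "physical_distance", "peak_lag"])
    r = p = float("nan")
    if len(df) >= 3:
        sd = df.spike_distance.to_numpy()
        pdist = df.physical_distance.to_numpy()
        if np.std(sd) > 0 and np.std(pdist) > 0:
            r, p = stats.pearsonr(sd, pdist)
    return df, float(r), float(p)
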
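"""Per-unit characterization.

Waveform shape features use the extracellular convention in which the *peak*
is the global minimum of the average waveform (initial depolarization) and
the *trough* is the maximum occurring after the peak; duration is the
peak-to-trough interval. Burst tendency is classified from the smoothed
log10 inter-spike-interval density via the void parameter,

    void = 1 - g(minimum) / sqrt(g(peak1) * g(peak2)),

where g is the density, peak1/peak2 are its two most prominent local maxima
and the minimum is taken between them. A void close to 1 indicates a deeply
bimodal ISI distribution, i.e. firing in bursts separated by long pauses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import AverageWaveform, BurstProfile, SpikeTrain, WaveformFeatures

__all__ = [
    "waveform_features",
    "spike_rate",
    "refractory_violation_fraction",
    "log_isi_density",
    "void_parameter",
    "classify_bursting",
    "burst_profile",
    "unit_yield",
    "unit_feature_table",
]

#: Histogram layout for the log10-ISI density (decades relative to 1 s).
LOG_ISI_RANGE = (-3.5, 1.5)
MIN_ISIS_FOR_BURST = 20


def waveform_features(w: AverageWaveform) -> WaveformFeatures:
    """Extract shape features from an average waveform.

    Raises
    ------
    ValueError
        If the waveform is too short or has no maximum after its minimum
        (e.g. a monotone segment), in which case the features are undefined.
    """
    v = w.samples
    if v.size < 8:
        raise ValueError("waveform too short for feature extraction (need >= 8 samples)")
    peak_idx = int(np.argmin(v))
    if peak_idx >= v.size - 1:
        raise ValueError("no samples after the waveform peak; features undefined")
    # earliest maximum strictly after the peak
    trough_idx = peak_idx + 1 + int(np.argmax(v[peak_idx + 1:]))
    peak_val = v[peak_idx]
    trough_val = v[trough_idx]
    if peak_val == 0:
        raise ValueError("zero peak value; trough/peak ratio undefined")
    centered = v - v.mean()
    denom = np.sqrt(np.sum(centered**2) * np.sum(centered[::-1] ** 2))
    symmetry = float(np.sum(centered * centered[::-1]) / denom) if denom > 0 else 0.0
    return WaveformFeatures(
        duration=(trough_idx - peak_idx) / w.sample_rate,
        amplitude=float(v.max() - v.min()),
        trough_peak_ratio=float(trough_val / peak_val),
        symmetry=symmetry,
        peak_index=peak_idx,
        trough_index=trough_idx,
    )


def spike_rate(t: SpikeTrain, duration: float) -> float:
    """Mean firing rate: spike count divided by recording duration (s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return t.n_spikes / duration


def refractory_violation_fraction(t: SpikeTrain, refractory: float = 0.002) -> float:
    """Fraction of consecutive ISIs at or below the refractory period.

    A well-isolated single unit should have little to no spikes 0-2 ms after
    spiking; returns 0 by convention for trains with fewer than two spikes.
    """
    if t.n_spikes < 2:
        return 0.0
    isis = np.diff(t.times)
    return float(np.mean(isis <= refractory))


def log_isi_density(t: SpikeTrain, bins_per_decade: int = 10, smooth: int = 3):
    """Normalized, boxcar-smoothed histogram of log10(ISI).

    Returns ``(bin_centers, density, n_isis)``. The histogram covers
    ``LOG_ISI_RANGE`` decades; ISIs outside the range are ignored. ``smooth``
    must be odd. The density sums to 1 whenever any ISI falls in range.
    """
    if smooth < 1 or smooth % 2 == 0:
        raise ValueError("smooth must be a positive odd integer")
    lo, hi = LOG_ISI_RANGE
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    isis = np.diff(t.times)
    isis = isis[isis > 0]
    if isis.size == 0:
        return centers, np.zeros(n_bins), 0
    hist, _ = np.histogram(np.log10(isis), bins=edges)
    dens = np.convolve(hist.astype(float), np.ones(smooth) / smooth, mode="same")
    total = dens.sum()
    if total > 0:
        dens = dens / total
    return centers, dens, int(isis.size)


def void_parameter(density: np.ndarray, prominence_frac: float = 0.05):
    """Void parameter of a log-ISI density, or None when unimodal.

    Locates the two most prominent local maxima (prominence at least
    ``prominence_frac`` of the density maximum); returns
    ``(void, (i_peak1, i_peak2), i_min)`` or ``(None, (), None)`` if fewer
    than two qualifying peaks exist.
    """
    density = np.asarray(density, dtype=float)
    if density.size == 0 or density.max() <= 0:
        return None, (), None
    peaks, props = signal.find_peaks(density, prominence=prominence_frac * density.max())
    if peaks.size < 2:
        return None, (), None
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    i1, i2 = int(top2.min()), int(top2.max())
    between = density[i1 + 1:i2]
    if between.size == 0:
        return None, (), None
    i_min = i1 + 1 + int(np.argmin(between))
    g_min = density[i_min]
    void = 1.0 - g_min / np.sqrt(density[i1] * density[i2])
    return float(void), (i1, i2), i_min


def classify_bursting(void: float | None, threshold: float = 0.7) -> bool:
    """A unit bursts iff its void parameter is defined and >= threshold."""
    return void is not None and void >= threshold


def burst_profile(t: SpikeTrain, bins_per_decade: int = 10, smooth: int = 3,
                  prominence_frac: float = 0.05, threshold: float = 0.7) -> BurstProfile:
    """Full burst classification for one spike train.

    Trains with fewer than 20 ISIs are non-bursting by convention (the
    density estimate is too noisy to call bimodality).
    """
    centers, density, n_isis = log_isi_density(t, bins_per_decade, smooth)
    if n_isis < MIN_ISIS_FOR_BURST:
        return BurstProfile(centers, density, None, False, (), None, n_isis)
    void, peaks, i_min = void_parameter(density, prominence_frac)
    return BurstProfile(centers, density, void, classify_bursting(void, threshold),
                        peaks, i_min, n_isis)


def unit_yield(labels_by_electrode: dict, n_functional: int) -> dict:
    """Percentage of functional electrodes bearing at least one unit per class.

    ``labels_by_electrode`` maps electrode id to an iterable of quality labels
    of the units found there (or a single label).
    """
    if n_functional < 1:
        raise ValueError("n_functional must be >= 1")
    counts: dict[str, int] = {}
    for labels in labels_by_electrode.values():
        if isinstance(labels, str):
            labels = [labels]
        for lab in set(labels):
            counts[lab] = counts.get(lab, 0) + 1
    return {lab: 100.0 * n / n_functional for lab, n in counts.items()}


def unit_feature_table(trains: dict, waveforms: dict, duration: float,
                       groups: dict | None = None) -> pd.DataFrame:
    """One row per unit with waveform, rate, QC and burst statistics.

    ``groups`` maps unit_id to "surface"/"depth" (optional). Units whose
    waveform has undefined features get NaNs rather than raising.
    """
    rows = []
    for uid, tr in trains.items():
        row = {"unit_id": uid, "group": (groups or {}).get(uid),
               "label": tr.label, "electrode_id": tr.electrode_id,
               "n_spikes": tr.n_spikes,
               "spike_rate_hz": spike_rate(tr, duration),
               "refractory_violation_fraction": refractory_violation_fraction(tr)}
        w = waveforms.get(uid)
        if w is not None:
            try:
                f = waveform_features(w)
                row.update(duration_ms=f.duration * 1000.0, amplitude_uv=f.amplitude,
                           trough_peak_ratio=f.trough_peak_ratio, symmetry=f.symmetry)
            except ValueError:
                pass
        prof = burst_profile(tr)
        row.update(void=prof.void, bursting=prof.bursting)
        rows.append(row)
    cols = ["unit_id", "group", "label", "electrode_id", "n_spikes", "spike_rate_hz",
            "refractory_violation_fraction", "duration_ms", "amplitude_uv",
            "trough_peak_ratio", "symmetry", "void", "bursting"]
    return pd.DataFrame(rows, columns=cols)
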
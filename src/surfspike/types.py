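"""Core data containers shared across the pipeline.

Conventions follow extracellular electrophysiology practice: spike times in
seconds, waveform voltages in microvolts, electrode coordinates in micrometres.
The waveform sign convention is that of surface/depth unit characterization:
the *peak* is the waveform minimum (initial depolarization) and the *trough*
is the maximum that occurs after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "AverageWaveform",
    "TimeSeries",
    "Envelope",
    "ElectrodeGeometry",
    "StimulusSession",
    "TrialCounts",
    "WaveformFeatures",
    "BurstProfile",
    "PairRecord",
    "ResponseSummary",
    "UnitSpec",
    "SessionConfig",
]


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D array")
    return a


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times for one unit.

    Parameters
    ----------
    unit_id : str
        Identifier of the sorted cluster.
    times : array of float
        Spike times in seconds, strictly increasing.
    label : str
        Sorting quality label: ``"SUA"``, ``"MUA"``, ``"noise"`` or ``"artifact"``.
    electrode_id : str, optional
        Contact the unit was detected on.
    """

    unit_id: str
    times: np.ndarray
    label: str = "SUA"
    electrode_id: str | None = None

    def __post_init__(self):
        t = _as_float_array(self.times)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"spike times of unit {self.unit_id!r} must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        """Return a copy keeping only spikes in ``[t0, t1]``."""
        m = (self.times >= t0) & (self.times <= t1)
        return SpikeTrain(self.unit_id, self.times[m], self.label, self.electrode_id)


@dataclass(frozen=True)
class AverageWaveform:
    """Mean action-potential snippet for one unit (microvolts vs. time)."""

    unit_id: str
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the first sample."""
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled signal (voltage or audio)."""

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self):
        s = _as_float_array(self.samples)
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class Envelope:
    """Nonnegative amplitude envelope, by convention at 200 Hz."""

    values: np.ndarray
    sample_rate: float = 200.0
    start_time: float = 0.0

    def __post_init__(self):
        v = _as_float_array(self.values)
        if v.size and v.min() < 0:
            raise ValueError("envelope values must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    def __call__(self, t) -> np.ndarray:
        """Evaluate the envelope at times ``t`` (seconds); 0 outside support."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values, left=0.0, right=0.0)


class ElectrodeGeometry:
    """3-D positions (um) of surface-grid and depth-shank contacts.

    Backed by a DataFrame with columns ``electrode_id, probe, x_um, y_um, z_um``
    where ``probe`` is ``"surface"`` or ``"depth"``. The surface grid lies in the
    z = 0 plane and depth-site z increases with insertion depth.
    """

    COLUMNS = ["electrode_id", "probe", "x_um", "y_um", "z_um"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"geometry table missing columns: {missing}")
        self.table = table.reset_index(drop=True)
        self._pos = {
            str(r.electrode_id): np.array([r.x_um, r.y_um, r.z_um], dtype=float)
            for r in self.table.itertuples()
        }

    def __contains__(self, electrode_id: str) -> bool:
        return str(electrode_id) in self._pos

    def position(self, electrode_id: str) -> np.ndarray:
        try:
            return self._pos[str(electrode_id)]
        except KeyError:
            raise KeyError(f"unknown electrode {electrode_id!r}") from None

    def ids(self, probe: str | None = None) -> list[str]:
        t = self.table if probe is None else self.table[self.table.probe == probe]
        return [str(e) for e in t.electrode_id]

    @classmethod
    def default(cls, n_rows: int = 4, n_cols: int = 8, pitch_um: float = 200.0,
                n_depth_sites: int = 16, site_spacing_um: float = 50.0,
                insertion_depth_um: float = 600.0) -> "ElectrodeGeometry":
        """Default layout: an 8x4 surface grid at 200 um pitch plus a single
        depth shank through the grid centre, sites starting 600 um below the
        surface at 50 um spacing."""
        rows = []
        for i in range(n_rows * n_cols):
            r, c = divmod(i, n_cols)
            rows.append((f"S{i:02d}", "surface", c * pitch_um, r * pitch_um, 0.0))
        cx = (n_cols - 1) * pitch_um / 2.0
        cy = (n_rows - 1) * pitch_um / 2.0
        for j in range(n_depth_sites):
            rows.append((f"D{j:02d}", "depth", cx, cy, insertion_depth_um + j * site_spacing_um))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


@dataclass(frozen=True)
class StimulusSession:
    """Trial schedule for one recording session.

    ``envelopes`` maps each stimulus identity to its amplitude envelope,
    sampled relative to stimulus onset.
    """

    onsets: np.ndarray
    stimulus_ids: tuple
    envelopes: Mapping[str, Envelope]

    def __post_init__(self):
        o = _as_float_array(self.onsets)
        if o.size > 1 and np.any(np.diff(o) <= 0):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", o)
        object.__setattr__(self, "stimulus_ids", tuple(str(s) for s in self.stimulus_ids))
        if len(self.stimulus_ids) != o.size:
            raise ValueError("one stimulus id per onset required")

    def onsets_for(self, stimulus_id: str) -> np.ndarray:
        ids = np.asarray(self.stimulus_ids)
        return self.onsets[ids == stimulus_id]


@dataclass(frozen=True)
class TrialCounts:
    """Per-trial spike counts in fixed-width bins around stimulus onsets."""

    counts: np.ndarray  # (n_trials, n_bins) integers
    bin_width: float  # seconds
    window: tuple  # (t_pre, t_post) relative to onset, seconds

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (trials x bins)")
        object.__setattr__(self, "counts", c)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-centre times in seconds relative to stimulus onset."""
        n = self.counts.shape[1]
        return self.window[0] + (np.arange(n) + 0.5) * self.bin_width


@dataclass(frozen=True)
class WaveformFeatures:
    """Shape features of an average extracellular waveform."""

    duration: float  # s, peak-to-trough interval
    amplitude: float  # uV, max minus min
    trough_peak_ratio: float  # trough value / peak value (<= 0 for biphasic spikes)
    symmetry: float  # mirror-correlation index in [-1, 1]
    peak_index: int
    trough_index: int


@dataclass(frozen=True)
class BurstProfile:
    """Smoothed log10-ISI density and the bimodality (void) statistic."""

    bin_centers: np.ndarray  # log10(ISI / s)
    density: np.ndarray  # sums to 1 (all-zero when too few ISIs)
    void: float | None
    bursting: bool
    peak_indices: tuple = ()
    minimum_index: int | None = None
    n_isis: int = 0


@dataclass(frozen=True)
class PairRecord:
    """One depth-surface unit pair."""

    depth_unit: str
    surface_unit: str
    spike_distance: float
    physical_distance: float
    peak_lag: float | None  # ms; None when the correlogram is empty


@dataclass(frozen=True)
class ResponseSummary:
    """Stimulus-evoked response metrics for one unit."""

    unit_id: str
    best_stimulus_id: str | None
    lag: float | None  # ms, in [0, 200)
    pearson_r: float
    p_value: float
    significant: bool
    effect_size: float


@dataclass(frozen=True)
class UnitSpec:
    """Generative description of one synthetic unit.

    ``waveform_params = (peak_amp_uV, trough_amp_uV, duration_s)`` with
    ``peak_amp_uV < 0 < trough_amp_uV``.
    """

    unit_id: str
    group: str  # "surface" | "depth"
    baseline_rate: float  # Hz
    stimulus_gain: float  # Hz per unit envelope
    response_lag: float  # s
    bursting: bool
    intra_burst_isi: float  # s
    burst_rate: float  # Hz (burst-onset rate when bursting)
    waveform_params: tuple  # (peak_amp_uV, trough_amp_uV, duration_s)
    electrode_id: str

    def __post_init__(self):
        if self.group not in ("surface", "depth"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.baseline_rate < 0 or self.stimulus_gain < 0:
            raise ValueError("rates and gains must be nonnegative")
        if not (0 <= self.response_lag < 0.2):
            raise ValueError("response_lag must lie in [0, 0.2) s")
        peak, trough, dur = self.waveform_params
        if dur <= 0:
            raise ValueError("waveform duration must be positive")
        if not (peak < 0 < trough):
            raise ValueError("waveform convention requires peak_amp < 0 < trough_amp")


@dataclass(frozen=True)
class SessionConfig:
    """Trial schedule and coupling parameters of a synthetic session."""

    n_trials: int = 54
    isi_low: float = 7.0
    isi_high: float = 15.0
    sample_rate: float = 30000.0
    seed: int = 0
    env_rate: float = 200.0
    coupling_strength: float = 1.5
    coupling_scale_um: float = 300.0
    ou_tau: float = 0.1
    lead_in: float = 2.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.isi_low < self.isi_high:
            raise ValueError("require isi_low < isi_high")
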
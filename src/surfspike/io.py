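"""Plain-text and HDF5 session storage.

A session directory holds:

* ``spikes.csv``    — unit_id, time_s, label, electrode_id
* ``units.csv``     — generator unit specs (synthetic sessions only)
* ``events.csv``    — onset_s, stimulus_id
* ``envelope.csv``  — t_s, value, stimulus_id (envelope relative to onset)
* ``geometry.csv``  — electrode_id, probe, x_um, y_um, z_um
* ``waveforms.h5``  — group ``/waveforms/<unit_id>`` with a ``sample_rate`` attr
* ``session.yaml``  — duration and schedule metadata

Derived outputs (``unit_features.csv``, ``pairs.csv``, ``responses.csv``)
are written next to them by the CLI stages.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthdata import SyntheticSession
from .types import AverageWaveform, ElectrodeGeometry, Envelope, SpikeTrain, StimulusSession

__all__ = ["write_session", "read_session", "LoadedSession"]


def write_session(session: SyntheticSession, outdir: str) -> None:
    """Write a synthetic session to ``outdir`` (created if missing)."""
    os.makedirs(outdir, exist_ok=True)
    spikes = [(uid, t, tr.label, tr.electrode_id)
              for uid, tr in session.trains.items() for t in tr.times]
    pd.DataFrame(spikes, columns=["unit_id", "time_s", "label", "electrode_id"]) \
        .to_csv(os.path.join(outdir, "spikes.csv"), index=False)
    pd.DataFrame([{
        "unit_id": u.unit_id, "group": u.group, "baseline_rate": u.baseline_rate,
        "stimulus_gain": u.stimulus_gain, "response_lag": u.response_lag,
        "bursting": u.bursting, "intra_burst_isi": u.intra_burst_isi,
        "burst_rate": u.burst_rate, "peak_amp_uv": u.waveform_params[0],
        "trough_amp_uv": u.waveform_params[1], "duration_s": u.waveform_params[2],
        "electrode_id": u.electrode_id,
    } for u in session.population]).to_csv(os.path.join(outdir, "units.csv"), index=False)
    pd.DataFrame({"onset_s": session.stimulus.onsets,
                  "stimulus_id": session.stimulus.stimulus_ids}) \
        .to_csv(os.path.join(outdir, "events.csv"), index=False)
    env_rows = []
    for sid, env in session.stimulus.envelopes.items():
        env_rows.append(pd.DataFrame({"t_s": env.times, "value": env.values,
                                      "stimulus_id": sid}))
    pd.concat(env_rows, ignore_index=True) \
        .to_csv(os.path.join(outdir, "envelope.csv"), index=False)
    session.geometry.table.to_csv(os.path.join(outdir, "geometry.csv"), index=False)
    with h5py.File(os.path.join(outdir, "waveforms.h5"), "w") as f:
        grp = f.create_group("waveforms")
        for uid, w in session.waveforms.items():
            d = grp.create_dataset(uid, data=w.samples)
            d.attrs["sample_rate"] = w.sample_rate
    with open(os.path.join(outdir, "session.yaml"), "w") as f:
        yaml.safe_dump({"duration_s": float(session.duration),
                        "n_trials": int(session.config.n_trials),
                        "seed": int(session.config.seed)}, f)


class LoadedSession:
    """Session directory contents, re-assembled into pipeline containers."""

    def __init__(self, trains: dict, stimulus: StimulusSession, waveforms: dict,
                 geometry: ElectrodeGeometry, duration: float, units: pd.DataFrame | None):
        self.trains = trains
        self.stimulus = stimulus
        self.waveforms = waveforms
        self.geometry = geometry
        self.duration = duration
        self.units = units

    @property
    def groups(self) -> dict:
        if self.units is None:
            return {}
        return dict(zip(self.units.unit_id, self.units.group))


def read_session(indir: str) -> LoadedSession:
    spikes = pd.read_csv(os.path.join(indir, "spikes.csv"))
    trains = {}
    for uid, sub in spikes.groupby("unit_id", sort=True):
        sub = sub.sort_values("time_s")
        elec = sub.electrode_id.iloc[0] if "electrode_id" in sub else None
        lab = sub.label.iloc[0] if "label" in sub else "SUA"
        trains[str(uid)] = SpikeTrain(str(uid), np.unique(sub.time_s.to_numpy()),
                                      str(lab), None if pd.isna(elec) else str(elec))
    events = pd.read_csv(os.path.join(indir, "events.csv"))
    env_df = pd.read_csv(os.path.join(indir, "envelope.csv"))
    envelopes = {}
    for sid, sub in env_df.groupby("stimulus_id"):
        sub = sub.sort_values("t_s")
        dt = np.median(np.diff(sub.t_s.to_numpy())) if len(sub) > 1 else 0.005
        envelopes[str(sid)] = Envelope(sub.value.to_numpy(), 1.0 / dt)
    stimulus = StimulusSession(events.onset_s.to_numpy(),
                               tuple(str(s) for s in events.stimulus_id), envelopes)
    geometry = ElectrodeGeometry(pd.read_csv(os.path.join(indir, "geometry.csv")))
    waveforms = {}
    wf_path = os.path.join(indir, "waveforms.h5")
    if os.path.exists(wf_path):
        with h5py.File(wf_path, "r") as f:
            for uid, d in f["waveforms"].items():
                waveforms[uid] = AverageWaveform(uid, d[()], float(d.attrs["sample_rate"]))
    meta_path = os.path.join(indir, "session.yaml")
    if os.path.exists(meta_path):
        with open(meta_path) as f:
            duration = float(yaml.safe_load(f)["duration_s"])
    else:
        duration = float(max(tr.times.max(initial=0.0) for tr in trains.values())) + 1.0
    units = None
    units_path = os.path.join(indir, "units.csv")
    if os.path.exists(units_path):
        units = pd.read_csv(units_path)
    return LoadedSession(trains, stimulus, waveforms, geometry, duration, units)
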
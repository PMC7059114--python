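"""Session readers/writers and inclusion-criteria reporting.

A session directory holds one TSV per unit (``<unit_id>.tsv`` with a single
``time_s`` column) and a ``metadata.json`` file describing unit roles,
durations, optional soma geometry and stimulus metadata. Times are written
with 5 decimal places (0.05 ms, one sample at 20 kHz), so a read/write
round trip is the identity up to that quantum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .data_model import (
    AnalysisConfig,
    Role,
    Session,
    SomaGeometry,
    SpikeTrain,
    ValidationError,
)

METADATA_NAME = "metadata.json"
_TIME_FMT = "%.5f"


class SessionIOError(ValueError):
    """Raised on malformed session files."""


def write_session(session: Session, path: Union[str, Path]) -> Path:
    """Write a session to *path* (created if missing); returns the path.

    Output is byte-deterministic for a given session: fixed float formatting,
    sorted JSON keys, one file per unit.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"units": [], "stimulus_duration": session.stimulus_duration}
    for uid in sorted(session.trains):
        tr = session.trains[uid]
        entry: dict = {
            "unit_id": uid,
            "role": tr.role.value,
            "duration": round(tr.duration, 5),
            "file": f"{uid}.tsv",
        }
        if uid in session.geometry:
            entry["geometry"] = asdict(session.geometry[uid])
        meta["units"].append(entry)
        with open(path / f"{uid}.tsv", "w") as fh:
            fh.write("time_s\n")
            for t in tr.times:
                fh.write(_TIME_FMT % t + "\n")
    if session.stimulus_onsets is not None:
        meta["stimulus_onsets"] = [round(float(t), 5) for t in session.stimulus_onsets]
    if session.triggered_spike_times is not None:
        meta["triggered_spike_times"] = [
            round(float(t), 5) for t in session.triggered_spike_times
        ]
    if session.sampling_rate is not None:
        meta["sampling_rate"] = session.sampling_rate
    with open(path / METADATA_NAME, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_session(path: Union[str, Path]) -> Session:
    """Load a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / METADATA_NAME
    if not meta_path.exists():
        raise SessionIOError(f"missing {METADATA_NAME} in {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    trains: dict[str, SpikeTrain] = {}
    geometry: dict[str, SomaGeometry] = {}
    seen: set[str] = set()
    for entry in meta.get("units", []):
        uid = entry["unit_id"]
        if uid in seen:
            raise SessionIOError(f"duplicate unit id {uid!r}")
        seen.add(uid)
        fpath = path / entry.get("file", f"{uid}.tsv")
        times = _read_times(fpath)
        duration = float(entry["duration"])
        if times.size and times.max() > duration:
            row = int(np.argmax(times > duration)) + 1
            raise SessionIOError(
                f"{fpath.name}: time exceeds duration at data row {row}"
            )
        if times.size and np.any(np.diff(times) <= 0):
            row = int(np.argmax(np.diff(times) <= 0)) + 2
            raise SessionIOError(f"{fpath.name}: unsorted time at data row {row}")
        trains[uid] = SpikeTrain(
            times=times, duration=duration, role=Role(entry["role"]), unit_id=uid
        )
        if "geometry" in entry:
            geometry[uid] = SomaGeometry(**entry["geometry"])
    onsets = meta.get("stimulus_onsets")
    triggered = meta.get("triggered_spike_times")
    return Session(
        trains=trains,
        geometry=geometry,
        stimulus_onsets=np.asarray(onsets, dtype=float) if onsets is not None else None,
        stimulus_duration=float(meta.get("stimulus_duration", 0.060)),
        triggered_spike_times=(
            np.asarray(triggered, dtype=float) if triggered is not None else None
        ),
        sampling_rate=meta.get("sampling_rate"),
    )


def _read_times(fpath: Path) -> np.ndarray:
    if not fpath.exists():
        raise SessionIOError(f"missing spike-time file {fpath}")
    with open(fpath) as fh:
        header = fh.readline().strip()
        if header != "time_s":
            raise SessionIOError(f"{fpath.name}: expected header 'time_s'")
        vals = []
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                vals.append(float(line))
            except ValueError as exc:
                raise SessionIOError(
                    f"{fpath.name}: unparsable time at data row {i}"
                ) from exc
    return np.asarray(vals, dtype=float)


def write_session_hdf5(session: Session, path: Union[str, Path]) -> Path:
    """Single-file HDF5 mirror of the session directory layout."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        for uid, tr in session.trains.items():
            g = fh.create_group(f"units/{uid}")
            g.create_dataset("times", data=tr.times)
            g.attrs["role"] = tr.role.value
            g.attrs["duration"] = tr.duration
            if uid in session.geometry:
                g.attrs["geometry"] = json.dumps(asdict(session.geometry[uid]))
        fh.attrs["stimulus_duration"] = session.stimulus_duration
        if session.stimulus_onsets is not None:
            fh.create_dataset("stimulus_onsets", data=session.stimulus_onsets)
        if session.triggered_spike_times is not None:
            fh.create_dataset(
                "triggered_spike_times", data=session.triggered_spike_times
            )
    return path


def load_session_hdf5(path: Union[str, Path]) -> Session:
    """Load a session written by :func:`write_session_hdf5`."""
    import h5py

    trains: dict[str, SpikeTrain] = {}
    geometry: dict[str, SomaGeometry] = {}
    with h5py.File(path, "r") as fh:
        for uid, g in fh["units"].items():
            trains[uid] = SpikeTrain(
                times=g["times"][()],
                duration=float(g.attrs["duration"]),
                role=Role(g.attrs["role"]),
                unit_id=uid,
            )
            if "geometry" in g.attrs:
                geometry[uid] = SomaGeometry(**json.loads(g.attrs["geometry"]))
        onsets = fh["stimulus_onsets"][()] if "stimulus_onsets" in fh else None
        trig = (
            fh["triggered_spike_times"][()]
            if "triggered_spike_times" in fh
            else None
        )
        stim_dur = float(fh.attrs.get("stimulus_duration", 0.060))
    return Session(
        trains=trains,
        geometry=geometry,
        stimulus_onsets=onsets,
        stimulus_duration=stim_dur,
        triggered_spike_times=trig,
    )


def sessions_equal(a: Session, b: Session, tol: float = 5e-5) -> bool:
    """Equality of two sessions up to the stored-time quantum."""
    if set(a.trains) != set(b.trains):
        return False
    for uid in a.trains:
        ta, tb = a.trains[uid], b.trains[uid]
        if ta.role != tb.role or ta.n_spikes != tb.n_spikes:
            return False
        if abs(ta.duration - tb.duration) > tol:
            return False
        if ta.n_spikes and np.max(np.abs(ta.times - tb.times)) > tol:
            return False
    for x, y in ((a.stimulus_onsets, b.stimulus_onsets),
                 (a.triggered_spike_times, b.triggered_spike_times)):
        if (x is None) != (y is None):
            return False
        if x is not None and (len(x) != len(y) or
                              (len(x) and np.max(np.abs(np.asarray(x) - np.asarray(y))) > tol)):
            return False
    return True


def spontaneous_spikes(
    train: SpikeTrain,
    stimulus_onsets: Optional[np.ndarray],
    exclusion: float = 0.300,
) -> np.ndarray:
    """Spikes outside ``[onset, onset + exclusion]`` windows.

    With no stimuli, all spikes are spontaneous.
    """
    if stimulus_onsets is None or len(stimulus_onsets) == 0:
        return train.times.copy()
    ons = np.asarray(stimulus_onsets, dtype=float)
    idx = np.searchsorted(ons, train.times, side="right") - 1
    prev_onset = np.where(idx >= 0, ons[np.clip(idx, 0, None)], -np.inf)
    keep = train.times - prev_onset > exclusion
    keep |= idx < 0
    return train.times[keep]


@dataclass
class InclusionReport:
    """Pass/fail eligibility per analysis, with the underlying counts."""

    spontaneous_ccg_ok: bool
    n_spontaneous_in_spikes: int
    sensory_ok: bool
    n_trials_with_evoked_in: int
    cf_in_ok: bool
    n_in_spikes_near_cs: int

    def as_dict(self) -> dict:
        return asdict(self)


def apply_inclusion_criteria(
    session: Session, config: Optional[AnalysisConfig] = None
) -> InclusionReport:
    """Evaluate the published inclusion minima for one session.

    - spontaneous CCG analysis: >= 200 spontaneous IN spikes;
    - sensory analyses: >= 20 trials with a sensory-evoked IN spike
      (an IN spike within 0-20 ms of an onset);
    - CF-IN analysis: >= 200 IN spikes within +/-100 ms of complex spikes.
    """
    config = config or AnalysisConfig()
    in_train = _require_role(session, Role.IN)
    cs_train = session.first_by_role(Role.PC_COMPLEX)

    n_spont = 0
    if in_train is not None:
        n_spont = spontaneous_spikes(
            in_train, session.stimulus_onsets, config.spont_exclusion_after_onset
        ).size

    n_evoked_trials = 0
    if in_train is not None and session.stimulus_onsets is not None:
        fast_lo, fast_hi = config.fast_window
        for onset in session.stimulus_onsets:
            lo = np.searchsorted(in_train.times, onset + fast_lo, side="left")
            hi = np.searchsorted(in_train.times, onset + fast_hi, side="left")
            if hi > lo:
                n_evoked_trials += 1

    n_near_cs = 0
    if in_train is not None and cs_train is not None and cs_train.n_spikes:
        w = config.ccg_window
        lo = np.searchsorted(cs_train.times, in_train.times - w, side="left")
        hi = np.searchsorted(cs_train.times, in_train.times + w, side="right")
        n_near_cs = int(np.count_nonzero(hi > lo))

    return InclusionReport(
        spontaneous_ccg_ok=n_spont >= config.min_spontaneous_in_spikes,
        n_spontaneous_in_spikes=int(n_spont),
        sensory_ok=n_evoked_trials >= config.min_trials_evoked_in,
        n_trials_with_evoked_in=int(n_evoked_trials),
        cf_in_ok=n_near_cs >= config.min_in_spikes_near_cs,
        n_in_spikes_near_cs=int(n_near_cs),
    )


def _require_role(session: Session, role: Role):
    trains = session.by_role(role)
    if len(trains) > 1 and role != Role.IN:
        raise ValidationError(f"multiple {role.value} trains in session")
    return trains[0] if trains else None
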
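"""Core domain types shared by all analysis stages.

All times are stored in seconds. Display/reporting in milliseconds is the
responsibility of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

#: Absolute refractory floor for physical spike trains (seconds).
REFRACTORY_FLOOR = 0.5e-3

#: Quantization step of stored spike times: one sample at 20 kHz (seconds).
TIME_QUANTUM = 5e-5


class Role(str, Enum):
    """Functional identity of a recorded unit."""

    IN = "IN"
    PC_SIMPLE = "PC_SIMPLE"
    PC_COMPLEX = "PC_COMPLEX"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times of one unit.

    Parameters
    ----------
    times:
        Event times in seconds, strictly increasing, all in ``[0, duration]``.
    duration:
        Recording duration in seconds.
    role:
        Functional identity of the unit.
    unit_id:
        Unique identifier within a session.
    enforce_refractory:
        If True (default), consecutive events closer than the absolute
        refractory floor (0.5 ms) are rejected.
    """

    times: np.ndarray
    duration: float
    role: Role
    unit_id: str
    enforce_refractory: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValidationError(f"{self.unit_id}: times must be 1-D")
        if not np.all(np.isfinite(t)):
            raise ValidationError(f"{self.unit_id}: non-finite spike times")
        if self.duration <= 0:
            raise ValidationError(f"{self.unit_id}: duration must be positive")
        if t.size:
            d = np.diff(t)
            if np.any(d <= 0):
                row = int(np.argmax(d <= 0)) + 1
                raise ValidationError(
                    f"{self.unit_id}: times not strictly increasing at row {row}"
                )
            if t[0] < 0 or t[-1] > self.duration:
                row = 0 if t[0] < 0 else int(t.size - 1)
                raise ValidationError(
                    f"{self.unit_id}: time outside [0, duration] at row {row}"
                )
            if self.enforce_refractory and np.any(d < REFRACTORY_FLOOR - 1e-12):
                row = int(np.argmax(d < REFRACTORY_FLOOR - 1e-12)) + 1
                raise ValidationError(
                    f"{self.unit_id}: inter-spike interval below refractory "
                    f"floor ({REFRACTORY_FLOOR * 1e3:.2f} ms) at row {row}"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration

    def with_times(self, times: np.ndarray) -> "SpikeTrain":
        return replace(self, times=np.asarray(times, dtype=float))


@dataclass(frozen=True)
class SomaGeometry:
    """Soma position of one unit in the rotated recording frame (micrometres).

    Depth (``z_depth``) is measured from the pial surface, positive downward.
    """

    x_transverse: float
    y_sagittal: float
    z_depth: float
    pc_layer_depth: float
    dura_depth: float

    def __post_init__(self) -> None:
        if not self.dura_depth < self.pc_layer_depth:
            raise ValidationError(
                "dura_depth must be shallower (smaller) than pc_layer_depth"
            )

    @property
    def normalized_ml_position(self) -> float:
        """Position in the molecular layer: 0 at the PC layer, 1 at the dura."""
        return (self.pc_layer_depth - self.z_depth) / (
            self.pc_layer_depth - self.dura_depth
        )


@dataclass
class Session:
    """One paired recording: spike trains plus optional stimulus metadata."""

    trains: dict[str, SpikeTrain]
    geometry: dict[str, SomaGeometry] = field(default_factory=dict)
    stimulus_onsets: Optional[np.ndarray] = None
    stimulus_duration: float = 0.060
    triggered_spike_times: Optional[np.ndarray] = None
    sampling_rate: Optional[float] = None

    def __post_init__(self) -> None:
        for uid, tr in self.trains.items():
            if tr.unit_id != uid:
                raise ValidationError(
                    f"train key {uid!r} does not match unit_id {tr.unit_id!r}"
                )
        if self.stimulus_onsets is not None:
            ons = np.asarray(self.stimulus_onsets, dtype=float)
            if ons.size and np.any(np.diff(ons) <= 0):
                raise ValidationError("stimulus onsets must be strictly increasing")
            self.stimulus_onsets = ons
        if self.triggered_spike_times is not None:
            trig = np.asarray(self.triggered_spike_times, dtype=float)
            dur = self.duration
            if trig.size and (trig.min() < 0 or (dur and trig.max() > dur)):
                raise ValidationError("triggered spike times outside [0, duration]")
            self.triggered_spike_times = trig
        for uid in self.geometry:
            if uid not in self.trains:
                raise ValidationError(f"geometry references unknown unit {uid!r}")

    @property
    def duration(self) -> float:
        return max((tr.duration for tr in self.trains.values()), default=0.0)

    def by_role(self, role: Role) -> list[SpikeTrain]:
        return [tr for tr in self.trains.values() if tr.role == role]

    def first_by_role(self, role: Role) -> Optional[SpikeTrain]:
        trains = self.by_role(role)
        return trains[0] if trains else None


@dataclass
class AnalysisConfig:
    """All analysis tunables with their default values.

    Defaults follow the published procedure where one is stated (CCG window,
    bin sizes, 500 block-shuffle surrogates of 5 s blocks, |Z| > 3, 1000 ISI
    shuffles, inclusion minima); remaining values are documented conventions.
    """

    ccg_window: float = 0.100
    bin_size_coarse: float = 0.010
    bin_size_mid: float = 0.005
    bin_size_fine: float = 0.0005
    bin_size_latency: float = 0.001
    n_shuffles_ccg: int = 500
    shuffle_block: float = 5.0
    n_shuffles_isi: int = 1000
    z_threshold: float = 3.0
    min_spontaneous_in_spikes: int = 200
    min_trials_evoked_in: int = 20
    min_in_spikes_near_cs: int = 200
    post_cs_exclusion: float = 0.025
    baseline_pc: tuple[float, float] = (-0.100, -0.080)
    baseline_in: tuple[float, float] = (-0.100, 0.0)
    spont_exclusion_after_onset: float = 0.300
    fine_ccg_window: float = 0.020
    fine_baseline: tuple[float, float] = (-0.020, -0.010)
    trial_window: tuple[float, float] = (-0.200, 0.300)
    fast_window: tuple[float, float] = (0.0, 0.020)
    delayed_window: tuple[float, float] = (0.050, 0.120)
    cs_evoked_window: float = 0.100
    latency_bin: float = 0.002
    n_boot: int = 1000
    drop_partial_block: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for b in (
            self.bin_size_coarse,
            self.bin_size_mid,
            self.bin_size_fine,
            self.bin_size_latency,
        ):
            if b <= 0:
                raise ValidationError("bin sizes must be positive")
            n = self.ccg_window / b
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(
                    f"ccg_window {self.ccg_window} not an integer multiple of bin {b}"
                )
        if self.z_threshold <= 0 or self.n_shuffles_ccg <= 0:
            raise ValidationError("thresholds and shuffle counts must be positive")
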
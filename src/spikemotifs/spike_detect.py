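"""Threshold spike detection on raw traces and simple/complex splitting.

Spike time is the time of the first threshold-crossing sample of each
event, so correlogram lags are consistent with the triggering semantics.
Purkinje-cell events are split into simple and complex spikes by the
trace variance in the 3 ms following each spike; the two populations are
separated automatically with a two-class Otsu threshold on log-variance
(a manual threshold can be supplied instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .data_model import Role, SpikeTrain


class DetectionError(ValueError):
    pass


class Polarity(int, Enum):
    NEGATIVE = -1
    POSITIVE = 1


class SpikeLabel(str, Enum):
    SIMPLE = "SIMPLE"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class RawTrace:
    samples: np.ndarray
    sampling_rate: float
    unit_id: str

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.sampling_rate <= 0:
            raise DetectionError("sampling_rate must be positive")
        if not np.all(np.isfinite(s)):
            raise DetectionError("non-finite samples in trace")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class SpikeLabels:
    spike_times: np.ndarray
    labels: np.ndarray  # array of SpikeLabel values (str)
    post_spike_variance: np.ndarray
    threshold: Optional[float]  # variance threshold used (None if unimodal)


def detect_spikes(
    trace: RawTrace,
    threshold: float,
    polarity: Polarity = Polarity.NEGATIVE,
    dead_time: float = 0.5e-3,
) -> np.ndarray:
    """Times of first threshold crossings, separated by at least *dead_time*."""
    s = trace.samples * int(Polarity(polarity))
    thr = threshold * int(Polarity(polarity))
    above = s > thr
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        onsets = np.concatenate([[0], onsets[onsets != 0]])
    if onsets.size == 0:
        return np.empty(0)
    times = onsets / trace.sampling_rate
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead_time:
            kept.append(t)
    return np.asarray(kept)


def split_simple_complex(
    trace: RawTrace,
    spike_times: np.ndarray,
    variance_window: float = 0.003,
    manual_threshold: Optional[float] = None,
    min_log_separation: float = 1.0,
) -> SpikeLabels:
    """Label spikes SIMPLE/COMPLEX by post-spike trace variance.

    Variance is computed over ``(t, t + variance_window]``. Without a manual
    threshold the split uses Otsu on log-variance; if the resulting class
    means are separated by less than *min_log_separation* log-units the
    distribution is treated as unimodal: a warning is raised and all spikes
    are labelled SIMPLE. COMPLEX is always the high-variance class.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        raise DetectionError("split_simple_complex requires >= 2 spikes")
    fs = trace.sampling_rate
    n_win = int(round(variance_window * fs))
    variances = np.empty(st.size)
    for i, t in enumerate(st):
        i0 = int(round(t * fs)) + 1
        i1 = min(i0 + n_win, trace.samples.size)
        seg = trace.samples[i0:i1]
        variances[i] = float(np.var(seg)) if seg.size else 0.0
    if manual_threshold is not None:
        labels = np.where(
            variances > manual_threshold, SpikeLabel.COMPLEX.value, SpikeLabel.SIMPLE.value
        )
        return SpikeLabels(st, labels, variances, float(manual_threshold))
    logs = np.log(np.maximum(variances, 1e-300))
    thr_log = _otsu_1d(logs)
    hi = logs > thr_log
    if not hi.any() or hi.all() or (
        logs[hi].mean() - logs[~hi].mean() < min_log_separation
    ):
        warnings.warn(
            "post-spike variance distribution appears unimodal; "
            "labelling all spikes SIMPLE",
            stacklevel=2,
        )
        labels = np.full(st.size, SpikeLabel.SIMPLE.value)
        return SpikeLabels(st, labels, variances, None)
    labels = np.where(hi, SpikeLabel.COMPLEX.value, SpikeLabel.SIMPLE.value)
    return SpikeLabels(st, labels, variances, float(np.exp(thr_log)))


def _otsu_1d(values: np.ndarray, n_bins: int = 128) -> float:
    """Two-class Otsu threshold for a 1-D sample."""
    hist, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    best_t, best_var = centers[0], -1.0
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    mu_total = cmean[-1] / total
    for i in range(n_bins - 1):
        w0 = csum[i] / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cmean[i] / csum[i]
        mu1 = (cmean[-1] - cmean[i]) / (total - csum[i])
        between = w0 * w1 * (mu0 - mu1) ** 2
        if between > best_var:
            best_var, best_t = between, centers[i]
        _ = mu_total
    return float(best_t)


def derive_trains(
    labels: SpikeLabels,
    duration: float,
    unit_id: str = "pc",
) -> dict[str, SpikeTrain]:
    """Split labelled PC events into PC_SIMPLE and PC_COMPLEX trains."""
    st = labels.spike_times
    lab = labels.labels
    simple = st[lab == SpikeLabel.SIMPLE.value]
    cplx = st[lab == SpikeLabel.COMPLEX.value]
    return {
        f"{unit_id}_simple": SpikeTrain(
            times=simple, duration=duration, role=Role.PC_SIMPLE,
            unit_id=f"{unit_id}_simple",
        ),
        f"{unit_id}_complex": SpikeTrain(
            times=cplx, duration=duration, role=Role.PC_COMPLEX,
            unit_id=f"{unit_id}_complex",
        ),
    }
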
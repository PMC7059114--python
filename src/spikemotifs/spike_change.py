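"""Cumulative-sum net-spike-change curves and the shuffled-ISI test.

The net spike change pools target spikes around all events, forms the
cumulative count versus lag, subtracts a linear fit to the baseline segment
extrapolated over the whole window, and divides by the number of events.
The scalar read-out is the signed extremum of the residual over the
post-event window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import SpikeTrain


class SpikeChangeError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeChangeCurve:
    """Baseline-corrected cumulative spike change per event."""

    times: np.ndarray  # lag grid (seconds, relative to event)
    delta_spikes: np.ndarray  # residual cumulative spikes per event
    baseline_slope: float
    baseline_intercept: float
    n_events: int
    scalar_net_change: Optional[float]
    scalar_window: tuple[float, float]
    degenerate: bool


@dataclass(frozen=True)
class IsiTestResult:
    """Median target ISI around real events versus shuffled placements."""

    real_median_isi: float
    shuffle_medians: np.ndarray
    z: float
    p: float
    n_events_used: int
    n_events_skipped: int


def _cumulative_curve(
    rel: np.ndarray,
    grid: np.ndarray,
    baseline: tuple[float, float],
    n_events: int,
    scalar_window: tuple[float, float],
    min_baseline_spikes: int = 2,
) -> SpikeChangeCurve:
    cum = np.searchsorted(np.sort(rel), grid, side="right").astype(float)
    bmask = (grid >= baseline[0] - 1e-12) & (grid <= baseline[1] + 1e-12)
    n_base = int(
        np.count_nonzero((rel >= baseline[0]) & (rel <= baseline[1]))
    )
    degenerate = n_base < min_baseline_spikes
    if degenerate:
        slope = intercept = 0.0
    else:
        # centre the abscissa for numerical conditioning of the fit
        x0 = grid[bmask].mean()
        slope, c0 = np.polyfit(grid[bmask] - x0, cum[bmask], 1)
        intercept = c0 - slope * x0
    resid = (cum - (slope * grid + intercept)) / n_events
    if degenerate:
        scalar = None
    else:
        smask = (grid >= scalar_window[0] - 1e-12) & (grid <= scalar_window[1] + 1e-12)
        seg = resid[smask]
        scalar = float(seg[int(np.argmax(np.abs(seg)))])
    return SpikeChangeCurve(
        times=grid,
        delta_spikes=resid,
        baseline_slope=float(slope),
        baseline_intercept=float(intercept),
        n_events=n_events,
        scalar_net_change=scalar,
        scalar_window=scalar_window,
        degenerate=degenerate,
    )


def net_spike_change(
    event_times: np.ndarray,
    target: SpikeTrain,
    *,
    window: tuple[float, float] = (-0.100, 0.100),
    baseline: tuple[float, float] = (-0.100, -0.080),
    scalar_window: tuple[float, float] = (0.0, 0.100),
    grid_step: float = 0.001,
    duration: Optional[float] = None,
) -> SpikeChangeCurve:
    """Net target-spike change per event around *event_times*.

    Events whose lag window is truncated by the recording bounds are dropped
    (mirroring the correlogram edge rule). A baseline with fewer than two
    pooled target spikes yields a flagged (degenerate) curve with an
    undefined scalar.
    """
    ev = np.asarray(event_times, dtype=float)
    if ev.size == 0:
        raise SpikeChangeError("net_spike_change requires at least one event")
    dur = duration if duration is not None else target.duration
    lo, hi = window
    keep = (ev + lo >= 0) & (ev + hi <= dur)
    ev = ev[keep]
    if ev.size == 0:
        raise SpikeChangeError("all events fall within one window of the bounds")
    tgt = target.times
    i0 = np.searchsorted(tgt, ev + lo, side="left")
    i1 = np.searchsorted(tgt, ev + hi, side="right")
    rel = np.concatenate(
        [tgt[a:b] - e for a, b, e in zip(i0, i1, ev)]
    ) if ev.size else np.empty(0)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    return _cumulative_curve(rel, grid, baseline, int(ev.size), scalar_window)


def sensory_spike_change(
    trials,
    unit_id: str,
    *,
    baseline: tuple[float, float] = (-0.200, 0.0),
    span: tuple[float, float] = (0.0, 0.300),
    grid_step: float = 0.001,
    trial_mask: Optional[np.ndarray] = None,
) -> SpikeChangeCurve:
    """Stimulus-locked spike change for one unit of a trial set.

    Cumulative sum of all spike times across trials, linear fit to the
    pre-stimulus baseline extrapolated over the whole trace, subtracted,
    and divided by the number of trials.
    """
    rasters = trials.rasters[unit_id]
    if trial_mask is not None:
        rasters = [r for r, m in zip(rasters, trial_mask) if m]
    n_trials = len(rasters)
    if n_trials == 0:
        raise SpikeChangeError("sensory_spike_change requires at least one trial")
    rel = np.concatenate(rasters) if rasters else np.empty(0)
    grid = np.arange(baseline[0], span[1] + grid_step / 2, grid_step)
    return _cumulative_curve(
        rel, grid, baseline, n_trials, scalar_window=span
    )


def _containing_isis(
    events: np.ndarray, target_times: np.ndarray
) -> tuple[np.ndarray, int]:
    """ISI of the target interval containing each event.

    Events before the first or after the last target spike are skipped.
    Events landing exactly on a spike time belong to the following interval.
    """
    idx = np.searchsorted(target_times, events, side="right")
    ok = (idx >= 1) & (idx <= target_times.size - 1)
    isis = target_times[idx[ok]] - target_times[idx[ok] - 1]
    return isis, int(np.count_nonzero(~ok))


def triggered_isi_test(
    triggered_times: np.ndarray,
    target: SpikeTrain,
    *,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
) -> IsiTestResult:
    """Compare the median target ISI containing real events to medians from
    randomly placed hypothetical events.

    Each shuffle places as many uniform random times over the recording as
    there are real events, so the null mirrors the interval-length bias of
    the real sampling. ``p = (1 + #{|shuffle - mean| >= |real - mean|}) /
    (n + 1)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ev = np.asarray(triggered_times, dtype=float)
    if ev.size < 10:
        raise SpikeChangeError("triggered_isi_test requires >= 10 events")
    if target.n_spikes < 100:
        raise SpikeChangeError("triggered_isi_test requires >= 100 target spikes")
    dur = duration if duration is not None else target.duration
    tgt = target.times
    real_isis, n_skipped = _containing_isis(ev, tgt)
    if real_isis.size == 0:
        raise SpikeChangeError("no event falls inside a target ISI")
    real_median = float(np.median(real_isis))

    n_ev = ev.size
    fake = rng.uniform(0.0, dur, size=(n_shuffles, n_ev))
    idx = np.searchsorted(tgt, fake, side="right")
    ok = (idx >= 1) & (idx <= tgt.size - 1)
    isi_mat = np.where(
        ok, tgt[np.clip(idx, 1, tgt.size - 1)] - tgt[np.clip(idx, 1, tgt.size - 1) - 1],
        np.nan,
    )
    shuffle_medians = np.nanmedian(isi_mat, axis=1)
    mu = float(np.mean(shuffle_medians))
    sd = float(np.std(shuffle_medians, ddof=0))
    z = (real_median - mu) / sd if sd > 0 else np.inf * np.sign(real_median - mu)
    n_extreme = int(
        np.count_nonzero(np.abs(shuffle_medians - mu) >= abs(real_median - mu))
    )
    p = (1 + n_extreme) / (n_shuffles + 1)
    return IsiTestResult(
        real_median_isi=real_median,
        shuffle_medians=shuffle_medians,
        z=float(z),
        p=float(p),
        n_events_used=int(real_isis.size),
        n_events_skipped=n_skipped,
    )
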
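"""Stimulus-locked analysis: PSTHs, first-spike latencies, response
components and trial sorting."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .ccg import CCG, _baseline_bin_mask, _bin_edges
from .data_model import Role, Session, SpikeTrain
from .spike_change import SpikeChangeCurve, sensory_spike_change


class SensoryError(ValueError):
    pass


@dataclass
class TrialSet:
    """Stimulus-locked rasters with per-trial sort labels.

    ``rasters[unit_id][i]`` holds unit spike times relative to onset *i*
    within the trial window. Labels:

    - ``in_fast_response``: an IN spike in 0-20 ms after onset;
    - ``cs_evoked``: a complex spike within 100 ms of onset.
    """

    onsets: np.ndarray
    window: tuple[float, float]
    rasters: dict[str, list[np.ndarray]]
    roles: dict[str, Role]
    in_fast_response: np.ndarray = field(default=None)  # type: ignore[assignment]
    cs_evoked: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class LatencyDistribution:
    """Histogram of per-trial first-spike latencies and its peak."""

    bin_size: float
    edges: np.ndarray
    counts: np.ndarray
    peak_latency: float  # bin centre of the max count
    peak_ok: bool  # max count >= mean + 4 SD of counts
    count_mean: float
    count_sd: float
    n_trials_with_spike: int


def build_trials(
    session: Session,
    window: tuple[float, float] = (-0.200, 0.300),
    *,
    fast_window: tuple[float, float] = (0.0, 0.020),
    cs_window: float = 0.100,
) -> TrialSet:
    """Cut the session into stimulus-locked trials and label them."""
    if session.stimulus_onsets is None or session.stimulus_onsets.size == 0:
        raise SensoryError("session has no stimulus onsets")
    ons = session.stimulus_onsets
    span = window[1] - window[0]
    if ons.size > 1 and np.min(np.diff(ons)) < span - 1e-12:
        raise SensoryError("trial windows overlap: inter-onset gap < window span")
    rasters: dict[str, list[np.ndarray]] = {}
    roles: dict[str, Role] = {}
    for uid, tr in session.trains.items():
        roles[uid] = tr.role
        i0 = np.searchsorted(tr.times, ons + window[0], side="left")
        i1 = np.searchsorted(tr.times, ons + window[1], side="right")
        rasters[uid] = [tr.times[a:b] - o for a, b, o in zip(i0, i1, ons)]
    trials = TrialSet(
        onsets=ons.copy(), window=window, rasters=rasters, roles=roles
    )
    trials.in_fast_response, trials.cs_evoked = compute_trial_labels(
        trials, fast_window=fast_window, cs_window=cs_window
    )
    return trials


def compute_trial_labels(
    trials: TrialSet,
    *,
    fast_window: tuple[float, float] = (0.0, 0.020),
    cs_window: float = 0.100,
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (in_fast_response, cs_evoked) purely from the rasters."""
    n = trials.n_trials
    in_fast = np.zeros(n, dtype=bool)
    cs_ev = np.zeros(n, dtype=bool)
    for uid, role in trials.roles.items():
        if role == Role.IN:
            for i, r in enumerate(trials.rasters[uid]):
                if np.any((r >= fast_window[0]) & (r < fast_window[1])):
                    in_fast[i] = True
        elif role == Role.PC_COMPLEX:
            for i, r in enumerate(trials.rasters[uid]):
                if np.any((r >= 0) & (r <= cs_window)):
                    cs_ev[i] = True
    return in_fast, cs_ev


def psth(
    trials: TrialSet,
    unit_id: str,
    bin_size: float = 0.005,
    *,
    exclude_cs_trials: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean spike count per bin per trial; returns (bin lower edges, counts)."""
    lo, hi = trials.window
    edges = lo + bin_size * np.arange(int(round((hi - lo) / bin_size)) + 1)
    rasters = trials.rasters[unit_id]
    if exclude_cs_trials:
        rasters = [r for r, cs in zip(rasters, trials.cs_evoked) if not cs]
    if len(rasters) == 0:
        raise SensoryError("no trials left for PSTH")
    pooled = np.concatenate(rasters) if rasters else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    return edges[:-1], counts.astype(float) / len(rasters)


def first_spike_latency(
    trials: TrialSet,
    unit_id: str,
    bin_size: float = 0.002,
    *,
    max_latency: float = 0.100,
) -> LatencyDistribution:
    """Per-trial latency to first spike after onset, histogrammed.

    The peak is accepted (``peak_ok``) when the maximum bin count is at
    least 4 standard deviations above the mean bin count.
    """
    lats = []
    for r in trials.rasters[unit_id]:
        post = r[r > 0]
        if post.size:
            lats.append(post[0])
    if len(lats) < 1:
        raise SensoryError("no trial has a post-onset spike")
    lats = np.asarray(lats)
    n_bins = int(round(max_latency / bin_size))
    edges = bin_size * np.arange(n_bins + 1)
    counts, _ = np.histogram(lats[lats <= max_latency], bins=edges)
    counts = counts.astype(float)
    mu, sd = float(counts.mean()), float(counts.std(ddof=0))
    imax = int(np.argmax(counts))
    peak = float(edges[imax] + bin_size / 2)
    peak_ok = bool(counts[imax] >= mu + 4 * sd) and sd > 0
    return LatencyDistribution(
        bin_size=bin_size,
        edges=edges,
        counts=counts,
        peak_latency=peak,
        peak_ok=peak_ok,
        count_mean=mu,
        count_sd=sd,
        n_trials_with_spike=int(lats.size),
    )


def response_amplitudes(
    curve: SpikeChangeCurve,
    fast: tuple[float, float] = (0.0, 0.020),
    delayed: tuple[float, float] = (0.050, 0.120),
) -> dict:
    """Fast and net delayed response amplitudes from a spike-change curve.

    ``fast_amp`` is the maximum of the mean spike change in the fast window;
    ``delayed_amp`` is the maximum in the delayed window minus ``fast_amp``.
    """
    t, y = curve.times, curve.delta_spikes
    if t.size == 0:
        raise SensoryError("empty spike-change curve")
    if t[0] > fast[0] + 1e-12 or t[-1] < delayed[1] - 1e-12:
        raise SensoryError("curve does not span the requested windows")
    fmask = (t >= fast[0] - 1e-12) & (t <= fast[1] + 1e-12)
    dmask = (t >= delayed[0] - 1e-12) & (t <= delayed[1] + 1e-12)
    fast_amp = float(np.max(y[fmask]))
    delayed_amp = float(np.max(y[dmask]) - fast_amp)
    return {"fast_amp": fast_amp, "delayed_amp": delayed_amp}


def compare_trial_groups(
    trials: TrialSet,
    grouping: str,
    unit_id: str,
    window: tuple[float, float] = (0.020, 0.040),
    *,
    mode: str = "count",
    min_group: int = 5,
) -> dict:
    """Rank-sum comparison of per-trial spiking between trial groups.

    *grouping* is ``"in_fast_response"`` or ``"cs_evoked"``. ``mode="count"``
    compares per-trial spike counts in *window* normalized by the window
    span; ``mode="isi"`` compares the target ISI containing the group-mean
    evoked-response time of the IN unit.
    """
    labels = getattr(trials, grouping)
    rasters = trials.rasters[unit_id]
    if mode == "count":
        span = window[1] - window[0]
        vals = np.array(
            [np.count_nonzero((r >= window[0]) & (r < window[1])) / span
             for r in rasters]
        )
    elif mode == "isi":
        in_uid = next(u for u, ro in trials.roles.items() if ro == Role.IN)
        lat = []
        for r, lab in zip(trials.rasters[in_uid], labels):
            post = r[(r >= 0) & (r < 0.1)]
            if lab and post.size:
                lat.append(post[0])
        if not lat:
            raise SensoryError("no evoked responses to anchor the ISI read-out")
        anchor = float(np.mean(lat))
        vals = np.full(len(rasters), np.nan)
        for i, r in enumerate(rasters):
            j = np.searchsorted(r, anchor, side="right")
            if 1 <= j <= r.size - 1:
                vals[i] = r[j] - r[j - 1]
    else:
        raise SensoryError(f"unknown mode {mode!r}")
    g1 = vals[np.asarray(labels, dtype=bool) & np.isfinite(vals)]
    g0 = vals[~np.asarray(labels, dtype=bool) & np.isfinite(vals)]
    if g1.size < min_group or g0.size < min_group:
        raise SensoryError(
            f"group sizes {g1.size}/{g0.size} below minimum {min_group}"
        )
    stat, p = stats.ranksums(g1, g0)
    return {
        "n_true": int(g1.size),
        "n_false": int(g0.size),
        "mean_true": float(np.mean(g1)),
        "mean_false": float(np.mean(g0)),
        "statistic": float(stat),
        "p": float(p),
        "direction": int(np.sign(np.mean(g1) - np.mean(g0))),
    }


def evoked_ccg(
    trials: TrialSet,
    in_unit: str,
    pc_unit: str,
    bin_size: float = 0.005,
    *,
    window: float = 0.100,
    baseline_window: tuple[float, float] = (-0.100, -0.080),
    fast_window: tuple[float, float] = (0.0, 0.020),
    min_triggers: int = 20,
) -> CCG:
    """Correlogram of PC spikes around sensory-evoked fast IN spikes.

    Triggers are IN spikes within the fast window after onset, taken only
    from trials without an evoked complex spike. Lags beyond the trial
    window are unavailable, so triggers too close to the trial edges are
    dropped as in the spontaneous correlogram.
    """
    edges = _bin_edges(window, bin_size)
    lags = edges[:-1]
    counts = np.zeros(lags.size)
    n_trig = 0
    lo_w, hi_w = trials.window
    for i in range(trials.n_trials):
        if trials.cs_evoked[i]:
            continue
        r_in = trials.rasters[in_unit][i]
        r_pc = trials.rasters[pc_unit][i]
        trig = r_in[(r_in >= fast_window[0]) & (r_in < fast_window[1])]
        for t0 in trig:
            if t0 - window < lo_w or t0 + window > hi_w:
                continue
            c, _ = np.histogram(r_pc - t0, bins=edges)
            counts += c
            n_trig += 1
    if n_trig < min_triggers:
        raise SensoryError(
            f"only {n_trig} qualifying evoked triggers (minimum {min_triggers})"
        )
    counts /= n_trig
    bmask = _baseline_bin_mask(lags, bin_size, baseline_window)
    baseline_rate = float(counts[bmask].mean())
    return CCG(
        trigger_id=in_unit,
        target_id=pc_unit,
        bin_size=bin_size,
        lags=lags,
        counts=counts,
        n_triggers=n_trig,
        n_edge_dropped=0,
        baseline_window=baseline_window,
        baseline_rate=baseline_rate,
        baseline_flagged=baseline_rate == 0.0,
    )


def sensory_change_curve(
    trials: TrialSet,
    unit_id: str,
    *,
    baseline: tuple[float, float] = (-0.200, 0.0),
    span: tuple[float, float] = (0.0, 0.300),
    exclude_cs_trials: bool = False,
    only_label: Optional[tuple[str, bool]] = None,
) -> SpikeChangeCurve:
    """Stimulus-locked spike-change curve with optional trial filtering."""
    mask = np.ones(trials.n_trials, dtype=bool)
    if exclude_cs_trials:
        mask &= ~trials.cs_evoked
    if only_label is not None:
        name, val = only_label
        mask &= getattr(trials, name) == val
    return sensory_spike_change(
        trials, unit_id, baseline=baseline, span=span, trial_mask=mask
    )
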
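"""Cross-correlograms, block-shuffle surrogate nulls and per-bin Z-scores.

The correlogram counts are *mean target-spike counts per bin per trigger*,
computed over a symmetric lag window with half-open bins ``[l, l + bin)``.
Significance testing follows the block-shuffle procedure: trigger times are
re-ordered in fixed-length blocks, surrogate correlograms are computed, the
original and surrogates are normalized to their respective baseline rates,
and the surrogate standard deviation (raw counts, divided by the original's
baseline rate) yields a per-bin standard score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .data_model import SpikeTrain


class CCGError(ValueError):
    """Raised on invalid correlogram inputs."""


class TriggerMode(str, Enum):
    ALL = "ALL"
    EXCLUDE_POST_CS = "EXCLUDE_POST_CS"
    ISI_RANGE = "ISI_RANGE"
    SENSORY_FAST = "SENSORY_FAST"
    TRIGGERED = "TRIGGERED"


@dataclass(frozen=True)
class CCG:
    """Binned trigger->target correlogram with baseline normalization."""

    trigger_id: str
    target_id: str
    bin_size: float
    lags: np.ndarray  # bin lower edges
    counts: np.ndarray  # mean target count per bin per trigger
    n_triggers: int
    n_edge_dropped: int
    baseline_window: tuple[float, float]
    baseline_rate: float  # mean counts/bin over baseline bins
    baseline_flagged: bool  # True when baseline_rate == 0

    @property
    def normalized(self) -> np.ndarray:
        if self.baseline_flagged:
            return np.full_like(self.counts, np.nan)
        return self.counts / self.baseline_rate

    def bin_index(self, lag: float) -> int:
        """Index of the bin whose lower edge is *lag* (within tolerance)."""
        i = int(np.argmin(np.abs(self.lags - lag)))
        if abs(self.lags[i] - lag) > 1e-9:
            raise CCGError(f"no bin with lower edge {lag}")
        return i


@dataclass(frozen=True)
class ShuffleNull:
    """Per-bin surrogate statistics from block-shuffled trigger times."""

    n_shuffles: int
    block_length: float
    bin_size: float
    lags: np.ndarray
    shuffle_mean_normalized: np.ndarray
    shuffle_sd_raw: np.ndarray
    shuffle_sd_normalized: np.ndarray  # raw SD / original baseline rate
    seed: Optional[int]
    usable: bool = True


@dataclass(frozen=True)
class ZScoredCCG:
    """CCG plus its surrogate null and the per-bin standard score."""

    ccg: CCG
    null: ShuffleNull
    z: np.ndarray

    @property
    def lags(self) -> np.ndarray:
        return self.ccg.lags

    @property
    def bin_size(self) -> float:
        return self.ccg.bin_size

    def z_at(self, lag: float) -> float:
        """Z of the bin whose lower edge is *lag* (seconds)."""
        return float(self.z[self.ccg.bin_index(lag)])


def select_trigger_spikes(
    trigger: SpikeTrain,
    complex_train: Optional[SpikeTrain] = None,
    mode: TriggerMode = TriggerMode.ALL,
    *,
    post_cs_exclusion: float = 0.025,
    isi_range: Optional[tuple[float, float]] = None,
    stimulus_onsets: Optional[np.ndarray] = None,
    sensory_window: float = 0.020,
    triggered_times: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Return the subset of trigger spike times selected by *mode*.

    EXCLUDE_POST_CS drops triggers with a complex spike in ``(t - excl, t]``;
    ISI_RANGE keeps triggers whose preceding inter-spike interval lies in
    ``[lo, hi)``; SENSORY_FAST keeps triggers within *sensory_window* after a
    stimulus onset; TRIGGERED returns the electrically triggered times.
    """
    mode = TriggerMode(mode)
    t = trigger.times
    if mode == TriggerMode.ALL:
        return t.copy()
    if mode == TriggerMode.EXCLUDE_POST_CS:
        if complex_train is None:
            raise CCGError("EXCLUDE_POST_CS requires a complex-spike train")
        cs = complex_train.times
        if cs.size == 0:
            return t.copy()
        lo = np.searchsorted(cs, t - post_cs_exclusion, side="right")
        hi = np.searchsorted(cs, t, side="right")
        return t[hi == lo]
    if mode == TriggerMode.ISI_RANGE:
        if isi_range is None:
            raise CCGError("ISI_RANGE requires isi_range=(lo, hi)")
        lo, hi = isi_range
        if t.size < 2:
            return np.empty(0)
        isis = np.diff(t)
        keep = (isis >= lo) & (isis < hi)
        return t[1:][keep]
    if mode == TriggerMode.SENSORY_FAST:
        if stimulus_onsets is None:
            raise CCGError("SENSORY_FAST requires stimulus_onsets")
        ons = np.asarray(stimulus_onsets, dtype=float)
        idx = np.searchsorted(ons, t, side="right") - 1
        prev = np.where(idx >= 0, ons[np.clip(idx, 0, None)], -np.inf)
        rel = t - prev
        return t[(rel >= 0) & (rel < sensory_window)]
    if mode == TriggerMode.TRIGGERED:
        if triggered_times is None:
            raise CCGError("TRIGGERED requires triggered_times")
        return np.asarray(triggered_times, dtype=float)
    raise CCGError(f"unknown mode {mode}")  # pragma: no cover


def _bin_edges(window: float, bin_size: float) -> np.ndarray:
    n = int(round(2 * window / bin_size))
    return -window + bin_size * np.arange(n + 1)


def _baseline_bin_mask(
    lags: np.ndarray, bin_size: float, baseline_window: tuple[float, float]
) -> np.ndarray:
    lo, hi = baseline_window
    return (lags >= lo - 1e-9) & (lags + bin_size <= hi + 1e-9)


def compute_ccg(
    trigger_times: np.ndarray,
    target: SpikeTrain,
    bin_size: float,
    window: float = 0.100,
    baseline_window: tuple[float, float] = (-0.100, -0.080),
    *,
    trigger_id: str = "trigger",
    duration: Optional[float] = None,
) -> CCG:
    """Mean target-spike count per lag bin around each trigger spike.

    Triggers whose lag window is truncated by the recording bounds are
    dropped (and counted in ``n_edge_dropped``). ``baseline_rate`` is the
    mean count/bin over the bins fully inside *baseline_window*; a zero
    baseline is flagged and normalization is undefined.
    """
    trig = np.asarray(trigger_times, dtype=float)
    if trig.size == 0:
        raise CCGError("compute_ccg requires at least one trigger spike")
    dur = duration if duration is not None else target.duration
    edges = _bin_edges(window, bin_size)
    lags = edges[:-1]
    keep = (trig - window >= 0) & (trig + window <= dur)
    kept = trig[keep]
    n_edge = int(trig.size - kept.size)
    if kept.size == 0:
        raise CCGError("all triggers fall within one window of the bounds")
    idx = np.searchsorted(target.times, kept[:, None] + edges[None, :], side="left")
    total = (idx[:, 1:] - idx[:, :-1]).sum(axis=0).astype(float)
    counts = total / kept.size
    bmask = _baseline_bin_mask(lags, bin_size, baseline_window)
    if not bmask.any():
        raise CCGError("baseline window contains no whole bin")
    baseline_rate = float(counts[bmask].mean())
    return CCG(
        trigger_id=trigger_id,
        target_id=target.unit_id,
        bin_size=bin_size,
        lags=lags,
        counts=counts,
        n_triggers=int(kept.size),
        n_edge_dropped=n_edge,
        baseline_window=baseline_window,
        baseline_rate=baseline_rate,
        baseline_flagged=baseline_rate == 0.0,
    )


def _fast_lag_histogram(
    triggers: np.ndarray,
    target: np.ndarray,
    window: float,
    bin_size: float,
    nbins: int,
) -> np.ndarray:
    """Mean target count per lag bin per trigger via window gather + bincount.

    Used for the surrogate loop, where the per-edge search of
    :func:`compute_ccg` would dominate runtime.
    """
    if triggers.size == 0:
        return np.zeros(nbins)
    lo = np.searchsorted(target, triggers - window, side="left")
    hi = np.searchsorted(target, triggers + window, side="left")
    n_per = hi - lo
    total = int(n_per.sum())
    if total == 0:
        return np.zeros(nbins)
    starts = np.zeros(triggers.size, dtype=np.int64)
    np.cumsum(n_per[:-1], out=starts[1:])
    flat = np.arange(total, dtype=np.int64) - np.repeat(starts, n_per) + np.repeat(lo, n_per)
    diffs = target[flat] - np.repeat(triggers, n_per)
    bins = np.clip(((diffs + window) / bin_size).astype(np.int64), 0, nbins - 1)
    return np.bincount(bins, minlength=nbins).astype(float) / triggers.size


def block_shuffle(
    trigger_times: np.ndarray,
    duration: float,
    block: float = 5.0,
    rng: Optional[np.random.Generator] = None,
    *,
    drop_partial: bool = False,
) -> np.ndarray:
    """Re-order fixed-length blocks of the recording, keeping within-block
    relative spike times.

    The recording is cut into ``ceil(duration / block)`` segments; the final
    partial segment keeps its own length (or is pinned in place when
    *drop_partial* is set). Spike count is conserved.
    """
    rng = rng if rng is not None else np.random.default_rng()
    t = np.asarray(trigger_times, dtype=float)
    if duration < 2 * block:
        raise CCGError("shuffle impossible: duration shorter than two blocks")
    n_full = int(duration // block)
    seg_lens = [block] * n_full
    partial = duration - n_full * block
    has_partial = partial > 1e-12
    if has_partial and not drop_partial:
        seg_lens.append(partial)
    if has_partial and drop_partial:
        t = t[t < n_full * block]
    starts = np.concatenate([[0.0], np.cumsum(seg_lens)[:-1]])
    n_seg = len(seg_lens)
    order = rng.permutation(n_seg)
    new_starts = np.concatenate([[0.0], np.cumsum(np.asarray(seg_lens)[order])[:-1]])
    offset_map = np.empty(n_seg)
    offset_map[order] = new_starts
    seg_idx = np.minimum((t // block).astype(int), n_seg - 1)
    out = (t - starts[seg_idx]) + offset_map[seg_idx]
    return np.sort(out)


def build_shuffle_null(
    trigger_times: np.ndarray,
    target: SpikeTrain,
    *,
    n_shuffles: int = 500,
    bin_size: float = 0.010,
    window: float = 0.100,
    baseline_window: tuple[float, float] = (-0.100, -0.080),
    block: float = 5.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    original_baseline_rate: Optional[float] = None,
) -> ShuffleNull:
    """Surrogate per-bin mean (normalized) and SD from block-shuffled triggers.

    The per-shuffle correlogram is normalized to its own baseline rate for
    the mean; the SD is taken on the raw (counts/bin/trigger) surrogates and
    additionally reported divided by the original correlogram's baseline rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trig = np.asarray(trigger_times, dtype=float)
    dur = duration if duration is not None else target.duration
    edges = _bin_edges(window, bin_size)
    lags = edges[:-1]
    bmask = _baseline_bin_mask(lags, bin_size, baseline_window)
    nbins = lags.size

    if original_baseline_rate is None:
        orig = compute_ccg(
            trig, target, bin_size, window, baseline_window, duration=dur
        )
        original_baseline_rate = orig.baseline_rate

    # All shuffled trigger sets at once: shuffling permutes block offsets, so
    # each surrogate is original offsets + permuted block starts.
    shuf = np.empty((n_shuffles, trig.size))
    for s in range(n_shuffles):
        shuf[s] = block_shuffle(trig, dur, block=block, rng=rng)

    counts = np.empty((n_shuffles, nbins))
    tgt = target.times
    for s in range(n_shuffles):
        t = shuf[s]
        t = t[(t - window >= 0) & (t + window <= dur)]
        counts[s] = _fast_lag_histogram(t, tgt, window, bin_size, nbins)

    base = counts[:, bmask].mean(axis=1)
    ok = base > 0
    norm = np.full_like(counts, np.nan)
    norm[ok] = counts[ok] / base[ok, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_norm = np.nanmean(norm, axis=0)
    sd_raw = counts.std(axis=0, ddof=0)
    usable = n_shuffles > 1 and original_baseline_rate > 0
    sd_norm = (
        sd_raw / original_baseline_rate
        if original_baseline_rate > 0
        else np.full(nbins, np.nan)
    )
    return ShuffleNull(
        n_shuffles=n_shuffles,
        block_length=block,
        bin_size=bin_size,
        lags=lags,
        shuffle_mean_normalized=mean_norm,
        shuffle_sd_raw=sd_raw,
        shuffle_sd_normalized=sd_norm,
        seed=seed,
        usable=usable,
    )


def zscore_ccg(ccg: CCG, null: ShuffleNull) -> ZScoredCCG:
    """Per-bin standard score of the original correlogram against its null.

    ``z = (normalized - shuffle_mean_normalized) / (shuffle_sd_raw / baseline)``.
    Bins where the surrogate SD is zero get ``z = nan`` and are excluded from
    downstream classification.
    """
    if ccg.lags.size != null.lags.size or abs(ccg.bin_size - null.bin_size) > 1e-12:
        raise CCGError("mismatched binning between CCG and null")
    if np.max(np.abs(ccg.lags - null.lags)) > 1e-9:
        raise CCGError("mismatched lag grids between CCG and null")
    if ccg.baseline_flagged or not null.usable:
        z = np.full(ccg.lags.size, np.nan)
        return ZScoredCCG(ccg=ccg, null=null, z=z)
    denom = null.shuffle_sd_raw / ccg.baseline_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ccg.normalized - null.shuffle_mean_normalized) / denom
    z[denom == 0] = np.nan
    return ZScoredCCG(ccg=ccg, null=null, z=z)


def zscored_ccg(
    trigger_times: np.ndarray,
    target: SpikeTrain,
    *,
    bin_size: float = 0.010,
    window: float = 0.100,
    baseline_window: tuple[float, float] = (-0.100, -0.080),
    n_shuffles: int = 500,
    block: float = 5.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    trigger_id: str = "trigger",
    duration: Optional[float] = None,
) -> ZScoredCCG:
    """Convenience wrapper: CCG + surrogate null + Z in one call."""
    ccg = compute_ccg(
        trigger_times,
        target,
        bin_size,
        window,
        baseline_window,
        trigger_id=trigger_id,
        duration=duration,
    )
    null = build_shuffle_null(
        trigger_times,
        target,
        n_shuffles=n_shuffles,
        bin_size=bin_size,
        window=window,
        baseline_window=baseline_window,
        block=block,
        rng=rng,
        seed=seed,
        duration=duration,
        original_baseline_rate=ccg.baseline_rate,
    )
    return zscore_ccg(ccg, null)


def threshold_crossing_latency(
    zscored: ZScoredCCG, sign: int, threshold: float = 3.0
) -> Optional[float]:
    """Lower edge of the first post-zero bin where z crosses the signed
    threshold; ``None`` if it never does."""
    if sign not in (-1, 1):
        raise CCGError("sign must be +1 or -1")
    lags = zscored.lags
    post = lags >= -1e-12
    z = zscored.z[post]
    lag = lags[post]
    if sign > 0:
        hits = z > threshold
    else:
        hits = z < -threshold
    hits &= np.isfinite(z)
    if not hits.any():
        return None
    return float(lag[int(np.argmax(hits))])


def synchrony_fraction(
    train_a: SpikeTrain, train_b: SpikeTrain, tol: float = 0.005
) -> dict:
    """Fraction of spikes of each train with a partner spike within +/-tol.

    Returns ``{"a_to_b": f, "b_to_a": f, "pair": mean}``.
    """
    if train_a.n_spikes == 0 or train_b.n_spikes == 0:
        raise CCGError("synchrony_fraction requires nonempty trains")

    def frac(src: np.ndarray, other: np.ndarray) -> float:
        lo = np.searchsorted(other, src - tol, side="left")
        hi = np.searchsorted(other, src + tol, side="right")
        return float(np.count_nonzero(hi > lo) / src.size)

    ab = frac(train_a.times, train_b.times)
    ba = frac(train_b.times, train_a.times)
    return {"a_to_b": ab, "b_to_a": ba, "pair": 0.5 * (ab + ba)}


def ccg_table(zscored: ZScoredCCG) -> "np.ndarray":
    """Structured rows (lag, count, normalized, shuffle_mean, shuffle_sd, z)
    ready for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lag_s": zscored.lags,
            "count": zscored.ccg.counts,
            "normalized": zscored.ccg.normalized,
            "shuffle_mean": zscored.null.shuffle_mean_normalized,
            "shuffle_sd": zscored.null.shuffle_sd_normalized,
            "z": zscored.z,
        }
    )
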
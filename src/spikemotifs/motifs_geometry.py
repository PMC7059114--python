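"""Motif classification from Z-scored correlograms, pair geometry, and
population-level statistics.

Classification windows (10 ms bins unless noted):

- IN->PC inhibition: z < -3 in the 0-10 ms bin; co-activation: z > +3 in
  the -10-0 ms bin.
- CF->IN excitation: z > +3 in the 0-10 or 10-20 ms bin; CF->IN inhibition:
  z < -3 in the 10-20 or 20-30 ms bin; combined requires both with the
  excitation threshold crossed earlier.
- IN-IN (5 ms bins): co-activation z > +3 and inhibition z < -3 within
  +/-10 ms lag; gap-junction synchrony requires significant fine-bin
  (0.5 ms) peaks at both +1 and -1 ms lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ccg import ZScoredCCG, threshold_crossing_latency
from .data_model import SomaGeometry


class MotifError(ValueError):
    pass


@dataclass
class MotifCall:
    """Per-pair motif flags with the statistics that back them."""

    pair_id: str
    flags: dict[str, bool] = field(default_factory=dict)
    supporting: dict[str, dict] = field(default_factory=dict)

    def set(self, name: str, value: bool, **support) -> None:
        self.flags[name] = bool(value)
        self.supporting[name] = support


@dataclass(frozen=True)
class PairGeometry:
    transverse_distance: float
    sagittal_distance: float
    ml_depth_distance: float
    normalized_ml_position_a: float
    normalized_ml_position_b: float


def _sig(z: float, threshold: float, sign: int) -> bool:
    if not np.isfinite(z):
        return False
    return z > threshold if sign > 0 else z < -threshold


def classify_in_pc(
    zscored: ZScoredCCG, threshold: float = 3.0, pair_id: str = "pair"
) -> MotifCall:
    """Inhibition (0-10 ms bin) and co-activation (-10-0 ms bin) flags."""
    call = MotifCall(pair_id=pair_id)
    z_inh = zscored.z_at(0.0)
    z_co = zscored.z_at(-0.010)
    call.set(
        "in_pc_inhibition",
        _sig(z_inh, threshold, -1),
        z=z_inh,
        window=(0.0, 0.010),
        normalized=float(zscored.ccg.normalized[zscored.ccg.bin_index(0.0)]),
    )
    call.set(
        "in_pc_coactivation",
        _sig(z_co, threshold, +1),
        z=z_co,
        window=(-0.010, 0.0),
    )
    return call


def classify_cf_in(
    zscored: ZScoredCCG,
    threshold: float = 3.0,
    pair_id: str = "pair",
    zscored_fine: Optional[ZScoredCCG] = None,
) -> MotifCall:
    """CF->IN excitation / inhibition / combined flags from a complex-spike-
    triggered correlogram at 10 ms bins.

    Excitation: z > threshold in the 0-10 or 10-20 ms bin. Inhibition:
    z < -threshold in the 10-20 or 20-30 ms bin. Combined requires both and
    the excitation crossing to occur earlier (assessed on *zscored_fine*
    at 1 ms bins when provided, otherwise on the coarse bins).
    """
    z0, z10, z20 = (zscored.z_at(l) for l in (0.0, 0.010, 0.020))
    exc = _sig(z0, threshold, +1) or _sig(z10, threshold, +1)
    inh = _sig(z10, threshold, -1) or _sig(z20, threshold, -1)
    combined = False
    exc_lat = inh_lat = None
    if exc and inh:
        src = zscored_fine if zscored_fine is not None else zscored
        exc_lat = threshold_crossing_latency(src, +1, threshold)
        inh_lat = threshold_crossing_latency(src, -1, threshold)
        combined = (
            exc_lat is not None and inh_lat is not None and exc_lat < inh_lat
        )
    call = MotifCall(pair_id=pair_id)
    call.set(
        "cf_in_excitation", exc and not combined,
        z_0_10=z0, z_10_20=z10, windows=((0.0, 0.010), (0.010, 0.020)),
    )
    call.set(
        "cf_in_inhibition", inh and not combined,
        z_10_20=z10, z_20_30=z20, windows=((0.010, 0.020), (0.020, 0.030)),
    )
    call.set(
        "cf_in_combined", combined,
        excitation_latency=exc_lat, inhibition_latency=inh_lat,
    )
    return call


def _fine_peak_bins(zscored: ZScoredCCG, side: int, threshold: float) -> bool:
    """Significant positive peak in any 0.5 ms bin centred within
    [0.5, 1.5] ms on the given side of zero lag."""
    centers = zscored.lags + zscored.bin_size / 2
    mask = (centers * side >= 0.5e-3) & (centers * side <= 1.5e-3)
    z = zscored.z[mask]
    return bool(np.any(np.isfinite(z) & (z > threshold)))


def classify_in_in(
    z_ab: ZScoredCCG,
    z_ba: ZScoredCCG,
    fine_ab: Optional[ZScoredCCG] = None,
    threshold: float = 3.0,
    pair_id: str = "pair",
) -> MotifCall:
    """IN-IN co-activation / inhibition (5 ms bins, +/-10 ms lag) and
    gap-junction synchrony (0.5 ms bins, +/-1 ms peaks).

    Direction: inhibition A->B when the A-triggered correlogram shows a
    significant post-trigger deficit within 10 ms (and symmetrically);
    both directions significant is reported as bidirectional.
    """
    def lag_window_z(zs: ZScoredCCG) -> np.ndarray:
        mask = (zs.lags >= -0.010 - 1e-9) & (zs.lags + zs.bin_size <= 0.010 + 1e-9)
        return zs.z[mask]

    def post_deficit(zs: ZScoredCCG) -> bool:
        mask = (zs.lags >= -1e-12) & (zs.lags + zs.bin_size <= 0.010 + 1e-9)
        z = zs.z[mask]
        return bool(np.any(np.isfinite(z) & (z < -threshold)))

    co = bool(
        np.any(np.isfinite(lag_window_z(z_ab)) & (lag_window_z(z_ab) > threshold))
        or np.any(np.isfinite(lag_window_z(z_ba)) & (lag_window_z(z_ba) > threshold))
    )
    inh_ab = post_deficit(z_ab)
    inh_ba = post_deficit(z_ba)
    direction = None
    if inh_ab and inh_ba:
        direction = "bidirectional"
    elif inh_ab:
        direction = "a_to_b"
    elif inh_ba:
        direction = "b_to_a"
    gap = False
    if fine_ab is not None:
        gap = _fine_peak_bins(fine_ab, +1, threshold) and _fine_peak_bins(
            fine_ab, -1, threshold
        )
    call = MotifCall(pair_id=pair_id)
    call.set("in_in_inhibition", inh_ab or inh_ba, direction=direction,
             z_ab=lag_window_z(z_ab).tolist(), z_ba=lag_window_z(z_ba).tolist())
    call.set("in_in_coactivation", co)
    call.set("gap_junction_synchrony", gap)
    return call


def compute_pair_geometry(geom_a: SomaGeometry, geom_b: SomaGeometry) -> PairGeometry:
    """Plane-projected distances and normalized molecular-layer positions.

    Transverse-plane (horizontal) distance uses the (x, y) projection,
    sagittal-plane the (y, z) projection; depth distance is the absolute
    depth difference. Keeping the transverse plane orthogonal to the depth
    axis lets depth gradients be assessed among laterally close pairs.
    """
    dx = geom_a.x_transverse - geom_b.x_transverse
    dy = geom_a.y_sagittal - geom_b.y_sagittal
    dz = geom_a.z_depth - geom_b.z_depth
    return PairGeometry(
        transverse_distance=float(math.hypot(dx, dy)),
        sagittal_distance=float(math.hypot(dy, dz)),
        ml_depth_distance=float(abs(dz)),
        normalized_ml_position_a=float(geom_a.normalized_ml_position),
        normalized_ml_position_b=float(geom_b.normalized_ml_position),
    )


def prevalence_by_distance(
    flags: Sequence[bool],
    distances: Sequence[float],
    bin_edges: Sequence[float],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[dict]:
    """Fraction of flagged pairs per distance bin with bootstrap SDs.

    Pairs are resampled with replacement *within each bin*; empty bins are
    reported with ``fraction=None``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    flags = np.asarray(flags, dtype=bool)
    dist = np.asarray(distances, dtype=float)
    out = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (dist >= lo) & (dist < hi)
        n = int(mask.sum())
        if n == 0:
            out.append({"lo": lo, "hi": hi, "n": 0, "fraction": None, "sd": None})
            continue
        f = flags[mask]
        frac = float(f.mean())
        res = rng.integers(0, n, size=(n_boot, n))
        boot = f[res].mean(axis=1)
        out.append(
            {"lo": float(lo), "hi": float(hi), "n": n,
             "fraction": frac, "sd": float(boot.std(ddof=0))}
        )
    return out


def fisher_exact_small_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by summing hypergeometric probabilities of
    all tables (fixed margins) no more probable than the observed one.

    Ties are included with a relative tolerance of 1e-7.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise MotifError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return 1.0
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def depth_regression(
    normalized_counts: Sequence[float],
    ml_depth_distances: Sequence[float],
    transverse_distances: Optional[Sequence[float]] = None,
    max_transverse: float = 30.0,
) -> dict:
    """OLS of normalized 0-10 ms target count on depth distance, restricted
    to pairs within *max_transverse* um transverse distance."""
    y = np.asarray(normalized_counts, dtype=float)
    x = np.asarray(ml_depth_distances, dtype=float)
    if transverse_distances is not None:
        mask = np.asarray(transverse_distances, dtype=float) <= max_transverse
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise MotifError("depth_regression requires >= 3 pairs after filtering")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(x.size),
    }


def group_compare(samples: Sequence[np.ndarray], design: str = "unpaired") -> dict:
    """Rank-based group comparison.

    ``design``: ``"paired"`` (Wilcoxon signed-rank, 2 groups),
    ``"unpaired"`` (Wilcoxon rank-sum, 2 groups) or ``"multi"``
    (Kruskal-Wallis followed by Tukey-Kramer pairwise comparisons on ranks).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size < 3 for s in samples):
        raise MotifError("group sizes must be >= 3")
    if design == "paired":
        if len(samples) != 2:
            raise MotifError("paired design needs exactly 2 groups")
        diff = samples[0] - samples[1]
        if np.allclose(diff, 0):
            return {"statistic": 0.0, "p": 1.0, "design": design}
        stat, p = stats.wilcoxon(samples[0], samples[1])
        return {"statistic": float(stat), "p": float(p), "design": design}
    if design == "unpaired":
        if len(samples) != 2:
            raise MotifError("unpaired design needs exactly 2 groups")
        stat, p = stats.ranksums(samples[0], samples[1])
        return {"statistic": float(stat), "p": float(p), "design": design}
    if design == "multi":
        stat, p = stats.kruskal(*samples)
        pooled = np.concatenate(samples)
        ranks = stats.rankdata(pooled)
        rank_groups = []
        i = 0
        for s in samples:
            rank_groups.append(ranks[i:i + s.size])
            i += s.size
        hsd = stats.tukey_hsd(*rank_groups)
        pairwise = {}
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                pairwise[f"{a}-{b}"] = float(hsd.pvalue[a, b])
        return {
            "statistic": float(stat),
            "p": float(p),
            "pairwise": pairwise,
            "design": design,
        }
    raise MotifError(f"unknown design {design!r}")
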
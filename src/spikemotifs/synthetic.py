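"""Ground-truth conditional-intensity point-process simulator.

Units are simulated in dependency order. Each unit's conditional intensity
is its baseline rate times the product of active multiplicative coupling
kernels (from already-simulated source trains) times an optional shared
log-rate modulation, plus additive stimulus-locked components. Sampling
uses exact thinning of an upper-bounded hazard followed by absolute
refractory pruning; the baseline hazard is inflated by the refractory duty
cycle so empirical rates match their targets.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from enum import Enum
from typing import Callable, Optional

import numpy as np

from .data_model import Role, Session, SomaGeometry, SpikeTrain


class SimulationError(ValueError):
    pass


class KernelShape(str, Enum):
    BOX_GAIN = "BOX_GAIN"
    ALPHA = "ALPHA"


#: default unit naming convention used by the builders below
DEFAULT_ROLES = {
    "in": Role.IN,
    "in2": Role.IN,
    "pc_simple": Role.PC_SIMPLE,
    "pc_complex": Role.PC_COMPLEX,
}

#: support of an alpha kernel, in units of its time constant
_ALPHA_SUPPORT = 8.0


@dataclass(frozen=True)
class CouplingKernel:
    """Multiplicative coupling from *source* spikes onto the *target* hazard.

    BOX_GAIN multiplies the hazard by ``gain`` for ``width`` seconds starting
    ``onset`` after each source spike (gain < 1 inhibits, > 1 excites, 0 is a
    hard veto). ALPHA multiplies by ``1 + (gain - 1) * a(dt)`` where ``a``
    rises to 1 at ``onset + width`` and decays with time constant ``width``.
    """

    source: str
    target: str
    shape: KernelShape
    gain: float
    onset: float
    width: float

    def __post_init__(self) -> None:
        if self.gain < 0 or self.onset < 0 or self.width <= 0:
            raise SimulationError("kernel requires gain >= 0, onset >= 0, width > 0")

    @property
    def support(self) -> float:
        if self.shape == KernelShape.BOX_GAIN:
            return self.onset + self.width
        return self.onset + _ALPHA_SUPPORT * self.width

    def apply(self, mult: np.ndarray, times: np.ndarray, source_times: np.ndarray) -> None:
        """Multiply kernel factors into ``mult`` (aligned with sorted *times*)."""
        if self.shape == KernelShape.BOX_GAIN:
            for s in source_times:
                i0 = np.searchsorted(times, s + self.onset, side="left")
                i1 = np.searchsorted(times, s + self.onset + self.width, side="left")
                if i1 > i0:
                    mult[i0:i1] *= self.gain
        else:
            tau = self.width
            for s in source_times:
                i0 = np.searchsorted(times, s + self.onset, side="left")
                i1 = np.searchsorted(times, s + self.support, side="left")
                if i1 > i0:
                    dt = times[i0:i1] - s - self.onset
                    a = (dt / tau) * np.exp(1.0 - dt / tau)
                    mult[i0:i1] *= 1.0 + (self.gain - 1.0) * a

    def max_factor(self) -> float:
        return max(1.0, self.gain)


@dataclass(frozen=True)
class CommonInput:
    """Shared log-rate modulation applied to the listed target units."""

    amplitude: float  # SD of the log-rate modulation
    timescale: float  # OU correlation time (s)
    targets: tuple[str, ...]
    clip_sigma: float = 4.0


@dataclass(frozen=True)
class SensoryTruth:
    """Stimulus-locked additive components and evoked-complex-spike model.

    ``fast[unit] = (latency, jitter_sd, spikes_per_trial)`` adds a Gaussian
    rate bump per stimulus; ``delayed`` likewise but, when
    ``delayed_only_if_cs`` is set, only on trials with an evoked complex
    spike. Evoked complex spikes are inserted with probability
    ``cs_evoked_p`` at ``onset + N(cs_latency, cs_jitter)``.
    """

    fast: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    delayed: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    cs_evoked_p: float = 0.0
    cs_latency: float = 0.050
    cs_jitter: float = 0.010
    delayed_only_if_cs: bool = True


@dataclass
class GroundTruth:
    """Complete, serializable description of a simulated session."""

    rates: dict[str, float]
    roles: dict[str, Role] = field(default_factory=dict)
    kernels: list[CouplingKernel] = field(default_factory=list)
    latent_units: tuple[str, ...] = ()
    gap_junction_p: float = 0.0
    gap_junction_pair: Optional[tuple[str, str]] = None
    gap_junction_lag: float = 1.0e-3
    gap_junction_jitter: float = 1.0e-4
    common_input: Optional[CommonInput] = None
    sensory: Optional[SensoryTruth] = None
    refractory: float = 0.5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = {
                u: DEFAULT_ROLES.get(u, Role.IN) for u in self.rates
            }
        for u, r in self.rates.items():
            if r < 0:
                raise SimulationError(f"negative rate for unit {u}")
        if not 0 <= self.gap_junction_p <= 1:
            raise SimulationError("gap_junction_p must be in [0, 1]")
        for k in self.kernels:
            if k.source not in self.rates or k.target not in self.rates:
                raise SimulationError(
                    f"kernel references unknown unit {k.source}->{k.target}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roles"] = {u: r.value for u, r in self.roles.items()}
        d["kernels"] = [
            {**asdict(k), "shape": k.shape.value} for k in self.kernels
        ]
        if self.common_input is not None:
            d["common_input"] = asdict(self.common_input)
        if self.sensory is not None:
            d["sensory"] = asdict(self.sensory)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["roles"] = {u: Role(r) for u, r in d.get("roles", {}).items()}
        d["kernels"] = [
            CouplingKernel(
                source=k["source"], target=k["target"],
                shape=KernelShape(k["shape"]), gain=k["gain"],
                onset=k["onset"], width=k["width"],
            )
            for k in d.get("kernels", [])
        ]
        if d.get("common_input"):
            ci = dict(d["common_input"])
            ci["targets"] = tuple(ci["targets"])
            d["common_input"] = CommonInput(**ci)
        if d.get("sensory"):
            s = dict(d["sensory"])
            s["fast"] = {u: tuple(v) for u, v in s.get("fast", {}).items()}
            s["delayed"] = {u: tuple(v) for u, v in s.get("delayed", {}).items()}
            d["sensory"] = SensoryTruth(**s)
        if d.get("latent_units"):
            d["latent_units"] = tuple(d["latent_units"])
        if d.get("gap_junction_pair"):
            d["gap_junction_pair"] = tuple(d["gap_junction_pair"])
        return cls(**d)


def simulate_conditional_intensity(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    ceiling: float,
    duration: float,
    rng: np.random.Generator,
    refractory: float = 0.5e-3,
) -> np.ndarray:
    """Exact thinning of a hazard bounded by *ceiling*, then refractory
    pruning. Raises if the evaluated rate exceeds the stated ceiling."""
    if not np.isfinite(ceiling) or ceiling < 0:
        raise SimulationError("rate ceiling must be finite and nonnegative")
    if ceiling == 0:
        return np.empty(0)
    n = rng.poisson(ceiling * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    lam = np.asarray(rate_fn(cand), dtype=float)
    if lam.size and lam.max() > ceiling * (1 + 1e-9):
        raise SimulationError(
            f"rate {lam.max():.3f} exceeds stated ceiling {ceiling:.3f}"
        )
    acc = cand[rng.uniform(0.0, ceiling, size=n) < lam]
    return _prune_refractory(acc, refractory)


def _prune_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    if times.size == 0 or refractory <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def gamma_renewal_train(
    rate: float,
    shape: float,
    duration: float,
    rng: np.random.Generator,
    refractory: float = 0.5e-3,
) -> np.ndarray:
    """Stationary gamma-renewal spike train with the given mean rate."""
    if rate <= 0:
        return np.empty(0)
    scale = 1.0 / (rate * shape)
    n_guess = int(rate * duration * 1.5) + 50
    isis = rng.gamma(shape, scale, size=n_guess)
    t = np.cumsum(isis) + rng.uniform(0, 1.0 / rate)
    while t.size and t[-1] < duration:
        more = np.cumsum(rng.gamma(shape, scale, size=n_guess)) + t[-1]
        t = np.concatenate([t, more])
    return _prune_refractory(t[t < duration], refractory)


def inject_isi_lengthening(
    times: np.ndarray, events: np.ndarray, delta: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Insert a *delta*-second gap at each event time, shifting later spikes.

    Lengthens exactly the inter-spike interval containing each event while
    preserving all other intervals. Events are mapped into the stretched
    time frame (each sits at the start of its own gap). Returns
    (new spike times, new event times, added duration).
    """
    ev = np.sort(np.asarray(events, dtype=float))
    shift = delta * np.searchsorted(ev, times, side="right")
    new_ev = ev + delta * np.arange(ev.size)
    return times + shift, new_ev, float(delta * ev.size)


def _ou_modulation(
    duration: float,
    timescale: float,
    rng: np.random.Generator,
    dt: float = 1.0e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance Ornstein-Uhlenbeck path sampled on a regular grid."""
    n = int(math.ceil(duration / dt)) + 2
    a = math.exp(-dt / timescale)
    noise = rng.normal(0.0, math.sqrt(1 - a * a), size=n)
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return dt * np.arange(n), x


class _SessionBuilder:
    """Simulates all units of one ground truth in dependency order."""

    def __init__(
        self,
        truth: GroundTruth,
        duration: float,
        rng: np.random.Generator,
        stimulus_onsets: Optional[np.ndarray] = None,
    ):
        self.truth = truth
        self.duration = duration
        self.rng = rng
        self.onsets = (
            np.asarray(stimulus_onsets, dtype=float)
            if stimulus_onsets is not None
            else None
        )
        self.trains: dict[str, np.ndarray] = {}
        self.cs_trials: Optional[np.ndarray] = None
        self._common_grid: Optional[tuple[np.ndarray, np.ndarray]] = None
        if truth.common_input is not None:
            self._common_grid = _ou_modulation(
                duration, truth.common_input.timescale, rng
            )

    # -- rate assembly -------------------------------------------------

    def _common_mult(self, times: np.ndarray) -> np.ndarray:
        ci = self.truth.common_input
        grid_t, grid_x = self._common_grid
        x = np.interp(times, grid_t, grid_x)
        x = np.clip(x, -ci.clip_sigma, ci.clip_sigma)
        return np.exp(ci.amplitude * x - 0.5 * ci.amplitude**2)

    def _sensory_additive(self, unit: str, times: np.ndarray) -> np.ndarray:
        sens = self.truth.sensory
        add = np.zeros(times.size)
        if sens is None or self.onsets is None:
            return add
        if unit in sens.fast:
            lat, jit, amp = sens.fast[unit]
            self._add_bumps(add, times, self.onsets, lat, jit, amp)
        if unit in sens.delayed:
            lat, jit, amp = sens.delayed[unit]
            if sens.delayed_only_if_cs and self.cs_trials is not None:
                ons = self.onsets[self.cs_trials]
            else:
                ons = self.onsets
            self._add_bumps(add, times, ons, lat, jit, amp)
        return add

    @staticmethod
    def _add_bumps(
        add: np.ndarray,
        times: np.ndarray,
        onsets: np.ndarray,
        latency: float,
        jitter: float,
        amplitude: float,
    ) -> None:
        norm = amplitude / (jitter * math.sqrt(2 * math.pi))
        half = 6 * jitter
        for o in onsets:
            c = o + latency
            i0 = np.searchsorted(times, c - half)
            i1 = np.searchsorted(times, c + half)
            if i1 > i0:
                dt = times[i0:i1] - c
                add[i0:i1] += norm * np.exp(-0.5 * (dt / jitter) ** 2)

    def _rate_fn(self, unit: str) -> tuple[Callable, float]:
        truth = self.truth
        base = truth.rates[unit]
        duty = 1.0 - base * truth.refractory
        base_adj = base / duty if duty > 0.5 else base
        my_kernels = [k for k in truth.kernels if k.target == unit]
        uses_common = (
            truth.common_input is not None
            and unit in truth.common_input.targets
        )

        def fn(times: np.ndarray) -> np.ndarray:
            mult = np.full(times.size, base_adj)
            if uses_common:
                mult *= self._common_mult(times)
            for k in my_kernels:
                k.apply(mult, times, self.trains[k.source])
            return mult + self._sensory_additive(unit, times)

        # ceiling: evaluate on a fine grid and add a safety margin; kernels
        # are piecewise-smooth so a 0.25 ms grid tracks the true maximum.
        grid = np.arange(0.0, self.duration, 0.25e-3)
        peak = float(fn(grid).max()) if grid.size else base_adj
        return fn, peak * 1.10 + 1.0

    # -- orchestration -------------------------------------------------

    def _topo_order(self) -> list[str]:
        units = list(self.truth.rates)
        deps = {u: {k.source for k in self.truth.kernels if k.target == u}
                for u in units}
        order: list[str] = []
        remaining = set(units)
        roles = self.truth.roles
        while remaining:
            ready = sorted(
                (u for u in remaining if deps[u] <= set(order)),
                # complex-spike units first: evoked complex spikes gate the
                # delayed sensory components of downstream units
                key=lambda u: (roles.get(u) != Role.PC_COMPLEX, u),
            )
            if not ready:
                raise SimulationError("cyclic kernel dependencies")
            order.extend(ready)
            remaining -= set(ready)
        return order

    def _insert_evoked_cs(self, unit: str) -> None:
        sens = self.truth.sensory
        if (
            sens is None
            or self.onsets is None
            or sens.cs_evoked_p <= 0
            or self.truth.roles.get(unit) != Role.PC_COMPLEX
        ):
            self.cs_trials = (
                np.zeros(self.onsets.size, dtype=bool)
                if self.onsets is not None
                else None
            )
            return
        hit = self.rng.uniform(size=self.onsets.size) < sens.cs_evoked_p
        lat = self.rng.normal(sens.cs_latency, sens.cs_jitter, size=self.onsets.size)
        new = self.onsets[hit] + np.maximum(lat[hit], 1e-3)
        merged = np.sort(np.concatenate([self.trains[unit], new]))
        self.trains[unit] = _prune_refractory(merged, self.truth.refractory)
        self.cs_trials = hit

    def _apply_gap_junction(self) -> None:
        truth = self.truth
        if truth.gap_junction_p <= 0 or truth.gap_junction_pair is None:
            return
        src, dst = truth.gap_junction_pair
        spikes = self.trains[src]
        hit = self.rng.uniform(size=spikes.size) < truth.gap_junction_p
        sign = np.where(self.rng.uniform(size=spikes.size) < 0.5, 1.0, -1.0)
        lag = sign * self.rng.normal(
            truth.gap_junction_lag, truth.gap_junction_jitter, size=spikes.size
        )
        partners = spikes[hit] + lag[hit]
        partners = partners[(partners > 0) & (partners < self.duration)]
        merged = np.sort(np.concatenate([self.trains[dst], partners]))
        self.trains[dst] = _prune_refractory(merged, truth.refractory)

    def run(self) -> Session:
        truth = self.truth
        for unit in self._topo_order():
            if truth.roles.get(unit) == Role.PC_COMPLEX and self.cs_trials is None:
                # complex spikes first so evoked CS can gate delayed bumps
                fn, ceiling = self._rate_fn(unit)
                self.trains[unit] = simulate_conditional_intensity(
                    fn, ceiling, self.duration, self.rng, truth.refractory
                )
                self._insert_evoked_cs(unit)
            else:
                fn, ceiling = self._rate_fn(unit)
                self.trains[unit] = simulate_conditional_intensity(
                    fn, ceiling, self.duration, self.rng, truth.refractory
                )
        self._apply_gap_junction()
        trains = {
            u: SpikeTrain(
                times=t, duration=self.duration,
                role=truth.roles.get(u, Role.IN), unit_id=u,
            )
            for u, t in self.trains.items()
            if u not in truth.latent_units
        }
        return Session(
            trains=trains,
            stimulus_onsets=self.onsets,
        )


def simulate_pair(
    truth: GroundTruth,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Session:
    """Jointly simulate all units of *truth* for *duration* seconds."""
    if rng is None:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    return _SessionBuilder(truth, duration, rng).run()


def simulate_sensory_session(
    truth: GroundTruth,
    n_trials: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    isi_range: tuple[float, float] = (1.0, 2.0),
) -> Session:
    """Simulate a stimulus session with uniform inter-stimulus intervals."""
    if n_trials < 1:
        raise SimulationError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    gaps = rng.uniform(isi_range[0], isi_range[1], size=n_trials)
    onsets = 0.5 + np.cumsum(gaps) - gaps[0]
    duration = float(onsets[-1] + 0.6)
    return _SessionBuilder(truth, duration, rng, stimulus_onsets=onsets).run()


# ---------------------------------------------------------------------------
# Convenience ground-truth builders
# ---------------------------------------------------------------------------

def truth_uncoupled(
    in_rate: float = 8.0,
    pc_rate: float = 26.4,
    cs_rate: float = 1.2,
    seed: int = 0,
) -> GroundTruth:
    """Independent IN / PC-simple / PC-complex trains at published rates."""
    return GroundTruth(
        rates={"in": in_rate, "pc_simple": pc_rate, "pc_complex": cs_rate},
        seed=seed,
    )


def truth_in_pc(
    gain: float = 0.7,
    width: float = 0.010,
    onset: float = 0.0,
    seed: int = 0,
    **rates,
) -> GroundTruth:
    """IN->PC multiplicative inhibition (default 0.7 gain for 10 ms)."""
    t = truth_uncoupled(seed=seed, **rates)
    t.kernels = [
        CouplingKernel("in", "pc_simple", KernelShape.BOX_GAIN, gain, onset, width)
    ]
    return t


def truth_cf_in(
    excitation_gain: Optional[float] = 3.0,
    excitation_onset: float = 0.002,
    excitation_tau: float = 0.010,
    inhibition_gain: Optional[float] = None,
    inhibition_onset: float = 0.010,
    inhibition_width: float = 0.020,
    seed: int = 0,
) -> GroundTruth:
    """Complex-spike -> IN coupling: spillover-like alpha excitation and/or
    delayed box inhibition."""
    t = truth_uncoupled(seed=seed)
    kernels = []
    if excitation_gain is not None:
        kernels.append(
            CouplingKernel(
                "pc_complex", "in", KernelShape.ALPHA,
                excitation_gain, excitation_onset, excitation_tau,
            )
        )
    if inhibition_gain is not None:
        kernels.append(
            CouplingKernel(
                "pc_complex", "in", KernelShape.BOX_GAIN,
                inhibition_gain, inhibition_onset, inhibition_width,
            )
        )
    t.kernels = kernels
    return t


def truth_in_in(
    inhibition_gain: Optional[float] = None,
    inhibition_width: float = 0.010,
    gap_junction_p: float = 0.0,
    common_amplitude: float = 0.0,
    common_timescale: float = 0.150,
    in_rate: float = 8.0,
    seed: int = 0,
) -> GroundTruth:
    """Two interneurons with optional inhibition, gap-junction coincidences
    and common-input co-modulation."""
    t = GroundTruth(
        rates={"in": in_rate, "in2": in_rate},
        seed=seed,
    )
    if inhibition_gain is not None:
        t.kernels = [
            CouplingKernel("in", "in2", KernelShape.BOX_GAIN,
                           inhibition_gain, 0.001, inhibition_width)
        ]
    if gap_junction_p > 0:
        t.gap_junction_p = gap_junction_p
        t.gap_junction_pair = ("in", "in2")
    if common_amplitude > 0:
        t.common_input = CommonInput(
            amplitude=common_amplitude,
            timescale=common_timescale,
            targets=("in", "in2"),
        )
    return t


def truth_sensory(
    pc_latency: float = 0.013,
    in_latency: float = 0.014,
    jitter: float = 0.001,
    fast_amplitude: float = 2.0,
    in_pc_gain: Optional[float] = 0.7,
    cs_evoked_p: float = 0.0,
    delayed_in_amplitude: float = 0.0,
    delayed_latency: float = 0.080,
    delayed_jitter: float = 0.015,
    seed: int = 0,
) -> GroundTruth:
    """Airpuff-like session: fast granule-cell components for PC and IN,
    optional evoked complex spikes gating a delayed IN component."""
    t = truth_uncoupled(seed=seed)
    if in_pc_gain is not None:
        t.kernels = [
            CouplingKernel("in", "pc_simple", KernelShape.BOX_GAIN,
                           in_pc_gain, 0.0, 0.010)
        ]
    t.sensory = SensoryTruth(
        fast={
            "pc_simple": (pc_latency, jitter, fast_amplitude),
            "in": (in_latency, jitter, fast_amplitude),
        },
        delayed=(
            {"in": (delayed_latency, delayed_jitter, delayed_in_amplitude)}
            if delayed_in_amplitude > 0
            else {}
        ),
        cs_evoked_p=cs_evoked_p,
    )
    return t


# ---------------------------------------------------------------------------
# Population generator with depth-graded circuit rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPair:
    """One simulated pair with its geometry and ground-truth motif flags."""

    session: Session
    geometry: dict[str, SomaGeometry]
    truth: GroundTruth
    true_flags: dict[str, bool]
    normalized_position: float


def simulate_population(
    n_pairs: int,
    duration: float = 600.0,
    seed: int = 0,
    *,
    ml_thickness: float = 200.0,
    dura_depth: float = 20.0,
    deep_cut: float = 0.4,
    superficial_cut: float = 0.6,
) -> list[PopulationPair]:
    """Population of IN-PC pairs obeying depth-graded microcircuit rules.

    - IN->PC inhibition exists for INs below ``superficial_cut``; its gain
      weakens linearly with normalized molecular-layer position (deep INs
      inhibit most strongly).
    - Complex-spike input inhibits deep INs (below ``deep_cut``) and excites
      superficial INs (above ``superficial_cut``) via a spillover-like
      alpha kernel.
    """
    rng = np.random.default_rng(seed)
    pc_layer = dura_depth + ml_thickness
    pairs: list[PopulationPair] = []
    for i in range(n_pairs):
        pos = float(rng.uniform(0.05, 0.95))
        connected = pos < superficial_cut
        flags = {
            "in_pc_inhibition": connected,
            "cf_in_excitation": pos > superficial_cut,
            "cf_in_inhibition": pos < deep_cut,
        }
        kernels = []
        if connected:
            gain = 0.55 + 0.5 * pos  # deep -> strong deficit
            kernels.append(
                CouplingKernel("in", "pc_simple", KernelShape.BOX_GAIN,
                               gain, 0.0, 0.010)
            )
        if flags["cf_in_excitation"]:
            kernels.append(
                CouplingKernel("pc_complex", "in", KernelShape.ALPHA,
                               3.0, 0.002, 0.010)
            )
        if flags["cf_in_inhibition"]:
            kernels.append(
                CouplingKernel("pc_complex", "in", KernelShape.BOX_GAIN,
                               0.2, 0.010, 0.020)
            )
        truth = GroundTruth(
            rates={"in": 8.0, "pc_simple": 26.4, "pc_complex": 1.2},
            kernels=kernels,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        session = simulate_pair(truth, duration, rng=rng)
        in_depth = pc_layer - pos * ml_thickness
        geometry = {
            "in": SomaGeometry(
                x_transverse=float(rng.uniform(0, 20)),
                y_sagittal=float(rng.uniform(0, 20)),
                z_depth=in_depth,
                pc_layer_depth=pc_layer,
                dura_depth=dura_depth,
            ),
            "pc_simple": SomaGeometry(
                x_transverse=0.0,
                y_sagittal=0.0,
                z_depth=pc_layer,
                pc_layer_depth=pc_layer,
                dura_depth=dura_depth,
            ),
        }
        session.geometry = geometry
        pairs.append(
            PopulationPair(
                session=session,
                geometry=geometry,
                truth=truth,
                true_flags=flags,
                normalized_position=pos,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Raw-trace synthesis for the detection stage
# ---------------------------------------------------------------------------

def synthesize_raw_trace(
    simple_times: np.ndarray,
    complex_times: np.ndarray,
    duration: float,
    sampling_rate: float = 20000.0,
    noise_sd: float = 0.05,
    amplitude: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    unit_id: str = "pc",
):
    """Superpose spike waveforms on white noise.

    Simple spikes are a brief negative biphasic wavelet; complex spikes add
    a 3 ms damped afterdischarge oscillation, so the post-spike variance
    separates the two classes.
    """
    from .spike_detect import RawTrace

    rng = rng if rng is not None else np.random.default_rng()
    n = int(round(duration * sampling_rate))
    trace = rng.normal(0.0, noise_sd, size=n)
    dt = 1.0 / sampling_rate

    # sharp onset so the threshold crossing sits within one sample of the
    # nominal spike time
    t_w = np.arange(0, 0.0012, dt)
    simple_w = -amplitude * np.exp(-((t_w - 0.00005) / 0.00005) ** 2)
    simple_w += 0.4 * amplitude * np.exp(-((t_w - 0.0004) / 0.00012) ** 2)
    t_a = np.arange(0, 0.003, dt)
    after = 0.8 * amplitude * np.sin(2 * np.pi * 600 * t_a) * np.exp(-t_a / 0.002)
    complex_w = np.concatenate([simple_w, np.zeros(max(0, t_a.size + 8 - t_w.size))])
    complex_w[8:8 + t_a.size] += after

    for times, w in ((simple_times, simple_w), (complex_times, complex_w)):
        for t in np.asarray(times, dtype=float):
            i0 = int(round(t * sampling_rate))
            i1 = min(i0 + w.size, n)
            if i0 < n:
                trace[i0:i1] += w[: i1 - i0]
    return RawTrace(samples=trace, sampling_rate=sampling_rate, unit_id=unit_id)
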
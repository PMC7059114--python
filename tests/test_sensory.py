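import numpy as np
import pytest

from spikemotifs.data_model import Role, Session
from spikemotifs.sensory import (
    SensoryError,
    build_trials,
    compare_trial_groups,
    compute_trial_labels,
    evoked_ccg,
    first_spike_latency,
    psth,
    response_amplitudes,
    sensory_change_curve,
)
from spikemotifs.spike_change import SpikeChangeCurve
from spikemotifs.synthetic import simulate_sensory_session, truth_sensory

from conftest import make_train


def _session_with(in_times, cs_times=(), pc_times=(), onsets=(2.0,), duration=20.0):
    trains = {
        "in": make_train(in_times, duration, Role.IN, "in"),
        "pc_simple": make_train(pc_times, duration, Role.PC_SIMPLE, "pc_simple"),
        "pc_complex": make_train(cs_times, duration, Role.PC_COMPLEX, "pc_complex"),
    }
    return Session(trains=trains, stimulus_onsets=np.asarray(onsets, dtype=float))


class TestBuildTrials:
    def test_forty_onsets_forty_trials(self, rng):
        onsets = 1.0 + np.arange(40) * 1.0
        s = _session_with([0.5], onsets=onsets, duration=60.0)
        trials = build_trials(s)
        assert trials.n_trials == 40

    def test_cs_evoked_window_boundary(self):
        s = _session_with([], cs_times=[2.099], onsets=[2.0])
        assert build_trials(s).cs_evoked[0]
        s = _session_with([], cs_times=[2.101], onsets=[2.0])
        assert not build_trials(s).cs_evoked[0]

    def test_in_fast_response_boundary(self):
        s = _session_with([2.019], onsets=[2.0])
        assert build_trials(s).in_fast_response[0]
        s = _session_with([2.021], onsets=[2.0])
        assert not build_trials(s).in_fast_response[0]

    def test_overlapping_windows_rejected(self):
        s = _session_with([0.5], onsets=[2.0, 2.3], duration=20.0)
        with pytest.raises(SensoryError, match="overlap"):
            build_trials(s)

    def test_no_onsets_rejected(self):
        s = Session(trains={"in": make_train([0.5], 20.0, Role.IN, "in")})
        with pytest.raises(SensoryError):
            build_trials(s)

    def test_labels_recomputable(self, rng):
        t = truth_sensory(fast_amplitude=2.0, cs_evoked_p=0.4, seed=0)
        sess = simulate_sensory_session(t, 40, seed=0)
        trials = build_trials(sess)
        in_fast, cs_ev = compute_trial_labels(trials)
        np.testing.assert_array_equal(in_fast, trials.in_fast_response)
        np.testing.assert_array_equal(cs_ev, trials.cs_evoked)


class TestPsth:
    def test_conservation(self, rng):
        t = truth_sensory(seed=1)
        sess = simulate_sensory_session(t, 30, seed=1)
        trials = build_trials(sess)
        _, counts = psth(trials, "pc_simple")
        total = sum(r.size for r in trials.rasters["pc_simple"])
        assert counts.sum() * trials.n_trials == pytest.approx(total)

    def test_zero_spikes_zero_psth(self):
        s = _session_with([], onsets=[2.0, 4.0])
        trials = build_trials(s)
        _, counts = psth(trials, "in")
        assert np.all(counts == 0)

    def test_flat_for_stationary_poisson(self, rng):
        onsets = 1.0 + np.arange(100) * 1.0
        times = np.sort(rng.uniform(0, 102, 3000))
        times = times[np.concatenate([[True], np.diff(times) >= 1e-3])]
        s = Session(
            trains={"in": make_train(times, 102.0, Role.IN, "in")},
            stimulus_onsets=onsets,
        )
        trials = build_trials(s)
        _, counts = psth(trials, "in", bin_size=0.025)
        mean = counts.mean()
        se = np.sqrt(mean / trials.n_trials)
        assert np.max(np.abs(counts - mean)) < 4 * se

    def test_exclude_cs_trials(self):
        s = _session_with([2.1, 4.1], cs_times=[2.05], onsets=[2.0, 4.0])
        trials = build_trials(s)
        _, counts_all = psth(trials, "in")
        _, counts_nocs = psth(trials, "in", exclude_cs_trials=True)
        assert counts_all.sum() == pytest.approx(1.0)  # 2 spikes / 2 trials
        assert counts_nocs.sum() == pytest.approx(1.0)  # 1 spike / 1 trial


class TestFirstSpikeLatency:
    def test_deterministic_latency_peak(self):
        onsets = 1.0 + np.arange(20) * 1.0
        s = _session_with(onsets + 0.013, onsets=onsets, duration=25.0)
        lat = first_spike_latency(build_trials(s), "in")
        assert lat.peak_latency == pytest.approx(0.013, abs=0.001)
        assert lat.peak_ok
        assert lat.counts.sum() == lat.n_trials_with_spike == 20

    def test_uniform_latencies_fail_peak_criterion(self, rng):
        fails = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            onsets = 1.0 + np.arange(40) * 1.0
            times = np.sort(onsets + r.uniform(0.0005, 0.0995, 40))
            s = _session_with(times, onsets=onsets, duration=45.0)
            lat = first_spike_latency(build_trials(s), "in")
            fails += not lat.peak_ok
        assert fails >= int(0.8 * n_seeds)

    def test_no_spikes_error(self):
        s = _session_with([], onsets=[2.0])
        with pytest.raises(SensoryError):
            first_spike_latency(build_trials(s), "in")


class TestResponseAmplitudes:
    def _curve(self, times, values):
        return SpikeChangeCurve(
            times=np.asarray(times), delta_spikes=np.asarray(values),
            baseline_slope=0.0, baseline_intercept=0.0, n_events=10,
            scalar_net_change=None, scalar_window=(0, 0.3), degenerate=False,
        )

    def test_monotone_rise_completed_early(self):
        t = np.arange(-0.2, 0.301, 0.001)
        y = np.where(t < 0.015, 0.0, 0.3)
        amp = response_amplitudes(self._curve(t, y))
        assert amp["fast_amp"] == pytest.approx(0.3)
        assert amp["delayed_amp"] == pytest.approx(0.0, abs=1e-12)

    def test_two_component_decomposition(self):
        t = np.arange(-0.2, 0.301, 0.001)
        y = np.where(t < 0.015, 0.0, 0.3) + np.where(t < 0.08, 0.0, 0.2)
        amp = response_amplitudes(self._curve(t, y))
        assert amp["fast_amp"] == pytest.approx(0.3)
        assert amp["delayed_amp"] == pytest.approx(0.2)

    def test_empty_curve_rejected(self):
        with pytest.raises(SensoryError):
            response_amplitudes(self._curve([], []))

    def test_short_curve_rejected(self):
        t = np.arange(0, 0.05, 0.001)
        with pytest.raises(SensoryError):
            response_amplitudes(self._curve(t, np.zeros_like(t)))


class TestCompareTrialGroups:
    def test_missing_group_rejected(self):
        s = _session_with([2.005, 4.005], onsets=[2.0, 4.0])
        trials = build_trials(s)  # all trials have fast IN response
        with pytest.raises(SensoryError, match="group sizes"):
            compare_trial_groups(trials, "in_fast_response", "pc_simple")

    def test_calibration_on_shuffled_labels(self):
        sig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            t = truth_sensory(fast_amplitude=1.0, in_pc_gain=None, seed=seed)
            sess = simulate_sensory_session(t, 40, seed=seed)
            trials = build_trials(sess)
            trials.in_fast_response = r.permutation(trials.in_fast_response)
            try:
                out = compare_trial_groups(trials, "in_fast_response", "pc_simple")
            except SensoryError:
                continue
            sig += out["p"] < 0.05
        assert sig <= 0.2 * n_seeds

    def test_inhibition_lowers_pc_spiking_in_responding_trials(self):
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            t = truth_sensory(fast_amplitude=1.0, in_pc_gain=0.2, seed=seed)
            # strengthen the read-out: widen the inhibition window
            t.kernels[0] = type(t.kernels[0])(
                "in", "pc_simple", t.kernels[0].shape, 0.2, 0.0, 0.030
            )
            sess = simulate_sensory_session(t, 80, seed=seed)
            trials = build_trials(sess)
            try:
                out = compare_trial_groups(
                    trials, "in_fast_response", "pc_simple", window=(0.020, 0.040)
                )
            except SensoryError:
                continue
            hits += out["direction"] == -1
        assert hits >= n_seeds - 2


class TestEvokedCCG:
    def test_too_few_triggers_ineligible(self):
        s = _session_with([2.005], onsets=[2.0])
        trials = build_trials(s)
        with pytest.raises(SensoryError, match="minimum"):
            evoked_ccg(trials, "in", "pc_simple")

    def _mean_post_window(self, in_pc_gain, seeds):
        vals, peaks, ses = [], [], []
        for seed in seeds:
            t = truth_sensory(fast_amplitude=2.0, in_pc_gain=in_pc_gain, seed=seed)
            sess = simulate_sensory_session(t, 200, seed=seed)
            trials = build_trials(sess)
            ccg = evoked_ccg(trials, "in", "pc_simple")
            vals.append(ccg.normalized[ccg.bin_index(0.005)])
            peaks.append(ccg.normalized[ccg.bin_index(0.0)])
            # per-bin counting SE of the normalized value
            ses.append(1 / np.sqrt(ccg.baseline_rate * ccg.n_triggers))
        return np.mean(vals), np.mean(peaks), np.mean(ses) / np.sqrt(len(seeds))

    def test_codrive_without_synapse_no_deficit(self):
        val, peak, se = self._mean_post_window(None, range(3))
        assert peak > 1.5  # co-drive peak near zero lag
        assert val > 1.0 - 3 * se  # 5-10 ms window within the null band

    def test_codrive_with_synapse_deficit(self):
        val, peak, se = self._mean_post_window(0.3, range(3, 6))
        assert peak > 1.5
        assert val < 1.0 - 3 * se
        assert val < 0.7


class TestSensoryChangeCurveFilters:
    def test_cs_gated_delayed_component(self):
        t = truth_sensory(
            fast_amplitude=1.0, in_pc_gain=None,
            cs_evoked_p=0.5, delayed_in_amplitude=1.5,
        )
        diffs = []
        for seed in range(4):
            t.seed = seed
            sess = simulate_sensory_session(t, 150, seed=seed)
            trials = build_trials(sess)
            with_cs = sensory_change_curve(
                trials, "in", only_label=("cs_evoked", True)
            )
            without_cs = sensory_change_curve(
                trials, "in", only_label=("cs_evoked", False)
            )
            a = response_amplitudes(with_cs)["delayed_amp"]
            b = response_amplitudes(without_cs)["delayed_amp"]
            diffs.append(a - b)
        assert np.mean(diffs) > 0.5
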
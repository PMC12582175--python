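import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicephys import (
    CCProtocol,
    Epoch,
    NeuronParams,
    SweepSet,
    adaptation_index,
    detect_spikes,
    fi_analysis,
    intrinsic_profile,
    passive_properties,
    simulate_current_clamp,
)
from helpers import FS, spike_family, triangular_spike_sweep

EPOCH = Epoch(0.2, 1.0, 100.0)


class TestDetectSpikes:
    def test_subthreshold_sweep_yields_no_spikes(self):
        v = np.full(int(1.4 * FS), -65.0)
        assert detect_spikes(v, FS, EPOCH) == []

    def test_peak_below_minus_10_not_counted(self):
        v = triangular_spike_sweep([0.5], peak_mv=-15.0)
        assert detect_spikes(v, FS, EPOCH) == []
        v_ok = triangular_spike_sweep([0.5], peak_mv=-5.0)
        assert len(detect_spikes(v_ok, FS, EPOCH)) == 1

    def test_piecewise_linear_ramp_matches_closed_form(self):
        """A 20 mV/ms ramp from -55 mV: threshold sits at the first ramp
        sample (central-difference slope there is exactly 10 mV/ms), and the
        symmetric triangle gives half-width = rise time."""
        dt_ms = 1000.0 / FS
        rise_ms = 55.0 / 20.0  # -55 -> 0 mV at 20 mV/ms
        v = triangular_spike_sweep([0.5], baseline_mv=-55.0, peak_mv=0.0,
                                   rise_ms=rise_ms, fall_ms=rise_ms)
        (spike,) = detect_spikes(v, FS, EPOCH)
        ramp_start_s = 0.5 - rise_ms / 1000.0
        assert spike.threshold_time_s == pytest.approx(ramp_start_s, abs=dt_ms / 1000.0)
        assert spike.threshold_mV == pytest.approx(-55.0, abs=20.0 * dt_ms)
        assert spike.amplitude_mV == pytest.approx(55.0, abs=20.0 * dt_ms)
        # half-crossings at -27.5 mV on both flanks: width = rise time
        assert spike.half_width_ms == pytest.approx(rise_ms, abs=2 * dt_ms)
        assert spike.max_rise_slope_mV_per_ms == pytest.approx(20.0, rel=0.01)
        assert spike.max_decay_slope_mV_per_ms == pytest.approx(-20.0, rel=0.01)

    def test_count_matches_simulator_ground_truth(self):
        ss, truth = simulate_current_clamp(NeuronParams(), seed=3)
        for i in range(ss.n_sweeps):
            ep = ss.stimulus[i][0]
            detected = detect_spikes(ss.data[i], ss.sampling_rate_hz, ep)
            in_epoch = [t for t in truth.spike_times_s[i]
                        if ep.onset_s <= t < ep.end_s]
            assert len(detected) == len(in_epoch)

    def test_features_invariant_to_time_shift(self):
        v = triangular_spike_sweep([0.5])
        shift_s = 0.1
        v2 = np.roll(v, int(shift_s * FS))
        (a,) = detect_spikes(v, FS, EPOCH)
        (b,) = detect_spikes(v2, FS, Epoch(EPOCH.onset_s + shift_s, 1.0, 100.0))
        assert b.peak_time_s - a.peak_time_s == pytest.approx(shift_s)
        assert b.amplitude_mV == a.amplitude_mV
        assert b.half_width_ms == pytest.approx(a.half_width_ms)


class TestFIAnalysis:
    def test_exactly_linear_family_recovers_slope_to_machine_precision(self):
        currents = np.arange(0.0, 450.0, 50.0)
        counts = (currents * 0.02).astype(int)  # 1 extra spike per 50 pA
        fi = fi_analysis(spike_family(counts, currents))
        assert fi.fi_gain_spikes_per_pA == pytest.approx(0.02, abs=1e-12)
        assert fi.rheobase_pA == 50.0
        assert fi.total_spike_output == counts.sum()

    def test_regression_range_ends_at_lowest_max_count_step(self):
        currents = [0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0]
        counts = [0, 0, 2, 4, 6, 6, 5]
        fi = fi_analysis(spike_family(counts, currents))
        assert fi.max_firing_sweep_pA == 200.0
        # OLS over [0..200] pA, counts [0,0,2,4,6]: slope = 800/25000
        assert fi.fi_gain_spikes_per_pA == pytest.approx(0.032, abs=1e-12)
        assert fi.total_spike_output == 12
        assert fi.rheobase_pA == 100.0

    def test_all_zero_counts_give_zero_gain_and_absent_rheobase(self):
        currents = np.arange(0.0, 250.0, 50.0)
        fi = fi_analysis(spike_family(np.zeros(len(currents), dtype=int), currents))
        assert fi.rheobase_pA is None
        assert fi.fi_gain_spikes_per_pA == 0.0
        assert fi.total_spike_output == 0

    def test_simulated_rheobase_is_first_suprathreshold_step(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = NeuronParams(r_mohm=rng.uniform(100, 250),
                             v_t_mv=rng.uniform(-50, -40))
            ss, truth = simulate_current_clamp(p, seed=seed)
            fi = fi_analysis(ss)
            spiking = [
                ss.stimulus[i][0].amplitude for i in range(ss.n_sweeps)
                if any(ss.stimulus[i][0].onset_s <= t < ss.stimulus[i][0].end_s
                       for t in truth.spike_times_s[i])
            ]
            assert fi.rheobase_pA == (min(spiking) if spiking else None)


class TestAdaptationIndex:
    def _family(self, times):
        v = triangular_spike_sweep(times, duration_s=1.4)
        return SweepSet(sampling_rate_hz=FS, clamp_mode="current_clamp",
                        data=v[None, :], stimulus=[[Epoch(0.2, 1.0, 100.0)]])

    def test_regular_even_train_scores_zero(self):
        times = 0.2 + (np.arange(8) + 0.5) / 8.0
        assert adaptation_index(self._family(times), 50.0) == 0.0

    def test_all_spikes_in_first_half_score_plus_one(self):
        times = 0.2 + np.linspace(0.05, 0.4, 5)
        assert adaptation_index(self._family(times), 50.0) == 1.0

    def test_five_then_two_spikes(self):
        times = np.concatenate([0.2 + np.linspace(0.05, 0.45, 5),
                                0.2 + np.array([0.8, 0.9])])
        assert adaptation_index(self._family(times), 50.0) == pytest.approx(3 / 7)

    def test_selects_sweep_nearest_twice_rheobase(self):
        fam = spike_family([2, 4, 6, 8], [50.0, 100.0, 150.0, 200.0])
        # rheobase 50 -> target 100: the 4-spike regular sweep scores 0
        assert adaptation_index(fam, 50.0) == 0.0

    def test_no_spikes_returns_none(self):
        fam = spike_family([0], [100.0])
        assert adaptation_index(fam, 50.0) is None

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.21, 1.15), min_size=1, max_size=15, unique=True))
    def test_index_always_within_unit_interval(self, times):
        times = [round(t, 3) for t in times]
        if len(set(times)) < len(times):
            return
        idx = adaptation_index(self._family(sorted(times)), 50.0)
        assert idx is not None and -1.0 <= idx <= 1.0


class TestPassiveProperties:
    def test_analytic_rc_trace_recovery(self):
        # R = 150 MOhm, tau = 15 ms, -20 pA: Rin 150, TC 15 ms, Cin 100 pF
        fs = FS
        n = int(1.4 * fs)
        t = np.arange(n) / fs
        v = np.full(n, -65.0)
        on, off = 0.2, 1.2
        in_step = (t >= on) & (t < off)
        v[in_step] += -3.0 * (1 - np.exp(-(t[in_step] - on) / 0.015))
        after = t >= off
        v[after] += -3.0 * (1 - np.exp(-(off - on) / 0.015)) * np.exp(-(t[after] - off) / 0.015)
        fam = SweepSet(sampling_rate_hz=fs, clamp_mode="current_clamp",
                       data=v[None, :], stimulus=[[Epoch(on, off - on, -20.0)]])
        p = passive_properties(fam)
        assert p.rin_MOhm == pytest.approx(150.0, rel=0.02)
        assert p.tc_ms == pytest.approx(15.0, rel=0.05)
        assert p.cin_pF == pytest.approx(1000.0 * p.tc_ms / p.rin_MOhm)
        assert p.sag_ratio == pytest.approx(1.0, abs=0.01)
        assert p.rmp_mV == pytest.approx(-65.0)

    def test_sag_ratio_from_peak_and_steady_deflections(self):
        # peak deflection -10 mV, last-50 ms mean -8 mV -> sag 1.25
        fs = FS
        n = int(1.4 * fs)
        t = np.arange(n) / fs
        v = np.full(n, -65.0)
        in_step = (t >= 0.2) & (t < 1.2)
        ts = t[in_step] - 0.2
        v[in_step] += np.where(ts < 0.1, -100.0 * ts, -8.0 - 2.0 * np.exp(-(ts - 0.1) / 0.05))
        fam = SweepSet(sampling_rate_hz=fs, clamp_mode="current_clamp",
                       data=v[None, :], stimulus=[[Epoch(0.2, 1.0, -20.0)]])
        assert passive_properties(fam, include_tc=False).sag_ratio == pytest.approx(1.25, rel=0.01)

    def test_sag_ratio_increases_with_sag_conductance(self):
        proto = CCProtocol(amplitudes_pa=(-20.0,))
        ratios = []
        for s in (0.0, 0.3, 0.8):
            p = NeuronParams(delta_t_mv=0.0, v_t_mv=1e9, sag_strength=s)
            ss, _ = simulate_current_clamp(p, proto, seed=0)
            ratios.append(passive_properties(ss, include_tc=False).sag_ratio)
        assert ratios[0] == pytest.approx(1.0, abs=0.02)
        assert ratios[0] < ratios[1] < ratios[2]


class TestIntrinsicProfile:
    def test_full_profile_from_default_family(self):
        p = NeuronParams(sag_strength=0.3)
        ss, truth = simulate_current_clamp(p, seed=11)
        prof = intrinsic_profile(ss)
        assert prof.rheobase_pA is not None and prof.rheobase_pA % 50.0 == 0.0
        assert prof.cin_pF == pytest.approx(1000.0 * prof.tc_ms / prof.rin_MOhm)
        assert prof.sag_ratio > 1.0
        assert -1.0 <= prof.adaptation_index <= 1.0
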
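import numpy as np
import pandas as pd
import pytest

from slicephys import (
    DetectionParams,
    EmptyAnalysisError,
    Epoch,
    EventGenParams,
    SweepSet,
    VCProtocol,
    acute_timecourse,
    detect_events,
    psc_kernel,
    simulate_voltage_clamp,
    summarize_events,
)
from slicephys.events import EVENT_COLUMNS, SUMMARY_COLUMNS

FS = 20_000.0
EXCLUDE_FIRST_SECOND = [Epoch(0.0, 1.0, 0.0)]


def quiet_trace(duration_s=5.0, noise_sd=0.0, seed=0):
    n = int(duration_s * FS)
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)


def add_event(trace, t_s, amp_pa, rise=0.5, decay=8.0):
    k = psc_kernel(rise, decay, FS)
    i0 = int(round(t_s * FS))
    seg = min(k.size, trace.size - i0)
    trace[i0 : i0 + seg] -= amp_pa * k[:seg]
    return trace


class TestDetectEvents:
    def test_single_noise_free_event_measured_exactly(self):
        trace = add_event(quiet_trace(), 2.0, 20.0)
        table = detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.amplitude_pa == pytest.approx(20.0, abs=0.5)
        assert row.onset_time_s == pytest.approx(2.0, abs=0.001)

    def test_subthreshold_events_not_detected(self):
        trace = quiet_trace(noise_sd=2.0, seed=1)
        for t in (1.5, 2.5, 3.5):
            add_event(trace, t, 6.0)
        assert len(detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)) == 0

    def test_events_within_local_max_period_merge(self):
        trace = add_event(add_event(quiet_trace(), 2.0, 20.0), 2.003, 20.0)
        table = detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)
        assert len(table) == 1

    def test_events_beyond_local_max_period_stay_separate(self):
        trace = add_event(add_event(quiet_trace(), 2.0, 20.0), 2.020, 20.0)
        table = detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)
        assert len(table) == 2

    def test_exclusion_epochs_drop_events(self):
        trace = add_event(add_event(quiet_trace(), 0.5, 20.0), 2.0, 20.0)
        table = detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)
        assert len(table) == 1 and table.iloc[0].peak_time_s > 1.0

    def test_full_exclusion_raises(self):
        with pytest.raises(EmptyAnalysisError):
            detect_events(quiet_trace(), FS, exclusions=[Epoch(0.0, 5.0, 0.0)])

    def test_drift_does_not_change_recovered_rate(self):
        base = EventGenParams(rate_hz=2.0, noise_sd_pa=2.0,
                              amp_mu_log=np.log(25), amp_sigma_log=0.2)
        drift = EventGenParams(rate_hz=2.0, noise_sd_pa=2.0,
                               amp_mu_log=np.log(25), amp_sigma_log=0.2,
                               drift_amp_pa=10.0, drift_period_s=5.0)
        freqs = []
        for params in (base, drift):
            ss, _ = simulate_voltage_clamp(params, VCProtocol(n_sweeps=4), seed=7)
            tables = [detect_events(ss.data[i], FS, exclusions=EXCLUDE_FIRST_SECOND)
                      for i in range(ss.n_sweeps)]
            freqs.append(summarize_events(ss, tables)["frequency_hz"].mean())
        assert abs(freqs[1] - freqs[0]) / freqs[0] < 0.02

    def test_amplitude_estimator_unbiased_on_noise_free_events(self):
        trace = quiet_trace(duration_s=10.0)
        amps = [12.0, 20.0, 35.0, 50.0]
        for t, a in zip((2.0, 4.0, 6.0, 8.0), amps):
            add_event(trace, t, a)
        table = detect_events(trace, FS, exclusions=EXCLUDE_FIRST_SECOND)
        assert len(table) == 4
        np.testing.assert_allclose(table["amplitude_pa"], amps, rtol=0.05)


class TestSummaries:
    def _sweepset(self, duration_s=30.0, n_sweeps=1):
        return SweepSet(sampling_rate_hz=FS, clamp_mode="voltage_clamp",
                        data=np.zeros((n_sweeps, int(duration_s * FS))))

    def _table(self, peak_times):
        return pd.DataFrame({
            "onset_time_s": np.asarray(peak_times) - 0.002,
            "peak_time_s": peak_times,
            "amplitude_pa": np.full(len(peak_times), 20.0),
            "rise_time_ms": np.full(len(peak_times), 1.5),
            "local_baseline_pa": np.zeros(len(peak_times)),
        }, columns=EVENT_COLUMNS)

    def test_29_events_in_30s_sweep_give_1_hz(self):
        table = self._table(np.linspace(1.5, 29.5, 29))
        summary = summarize_events(self._sweepset(), [table])
        assert summary.loc[0, "analysis_window_s"] == 29.0
        assert summary.loc[0, "frequency_hz"] == pytest.approx(1.0)

    def test_opto_sweep_discards_two_seconds(self):
        table = self._table(np.linspace(2.5, 29.5, 29))
        summary = summarize_events(self._sweepset(), [table], opto_present=True)
        assert summary.loc[0, "analysis_window_s"] == 28.0
        assert summary.loc[0, "frequency_hz"] == pytest.approx(29 / 28)

    def test_events_before_discard_are_not_counted(self):
        table = self._table([0.5, 1.5, 2.5])
        summary = summarize_events(self._sweepset(), [table])
        assert summary.loc[0, "n_events"] == 2

    def test_zero_events_give_zero_frequency_and_absent_kinetics(self):
        summary = summarize_events(self._sweepset(),
                                   [pd.DataFrame(columns=EVENT_COLUMNS)])
        assert summary.loc[0, "frequency_hz"] == 0.0
        assert np.isnan(summary.loc[0, "decay_tau_ms"])
        assert list(summary.columns) == SUMMARY_COLUMNS

    def test_decay_tau_recovered_from_averaged_event(self):
        params = EventGenParams(rate_hz=1.0, noise_sd_pa=2.0,
                                amp_mu_log=np.log(25), amp_sigma_log=0.2,
                                decay_tau_ms=8.0)
        ss, _ = simulate_voltage_clamp(params, VCProtocol(n_sweeps=3), seed=2)
        tables = [detect_events(ss.data[i], FS, exclusions=EXCLUDE_FIRST_SECOND)
                  for i in range(3)]
        summary = summarize_events(ss, tables)
        assert summary["decay_tau_ms"].mean() == pytest.approx(8.0, rel=0.10)


class TestAcuteTimecourse:
    def _summaries(self, freqs):
        return pd.DataFrame({"frequency_hz": freqs})

    def test_constant_frequency_gives_100_percent_everywhere(self):
        out = acute_timecourse(self._summaries([1.5] * 22))
        assert np.allclose(out["per_sweep"]["percent_of_baseline"], 100.0)

    def test_doubling_gives_200_percent(self):
        out = acute_timecourse(self._summaries([1.0, 1.0] + [2.0] * 20))
        drug = out["per_sweep"].query("phase == 'drug'")
        assert np.allclose(drug["percent_of_baseline"], 200.0)
        assert out["baseline_mean_hz"] == 1.0
        assert out["drug_mean_hz"] == 2.0

    def test_zero_baseline_flags_undefined_percent(self):
        out = acute_timecourse(self._summaries([0.0, 0.0] + [2.0] * 20))
        assert not out["percent_baseline_defined"]
        assert out["per_sweep"]["percent_of_baseline"].isna().all()

    def test_rate_step_recovered_from_simulated_sweeps(self):
        proto = VCProtocol(n_sweeps=1, sweep_s=30.0)
        freqs = []
        for i, rate in enumerate([1.0] * 2 + [3.0] * 4):
            params = EventGenParams(rate_hz=rate, noise_sd_pa=2.0,
                                    amp_mu_log=np.log(25), amp_sigma_log=0.2)
            ss, _ = simulate_voltage_clamp(params, proto, seed=50 + i)
            tables = [detect_events(ss.data[0], FS, exclusions=EXCLUDE_FIRST_SECOND)]
            freqs.append(summarize_events(ss, tables).loc[0, "frequency_hz"])
        out = acute_timecourse(self._summaries(freqs), n_drug_sweeps=4)
        ratio = out["drug_mean_hz"] / out["baseline_mean_hz"]
        # Poisson error on ~30-90 events per sweep
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_sweep_count_mismatch_rejected(self):
        with pytest.raises(Exception):
            acute_timecourse(self._summaries([1.0] * 5))
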
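"""Shared constructors for synthetic current-clamp fixtures."""

import numpy as np

from slicephys import Epoch, SweepSet

FS = 20_000.0


def triangular_spike_sweep(
    spike_times_s,
    fs=FS,
    duration_s=1.4,
    baseline_mv=-65.0,
    peak_mv=0.0,
    rise_ms=1.0,
    fall_ms=1.0,
):
    """Current-clamp sweep with triangular spikes at prescribed times.

    Each spike ramps linearly from baseline to ``peak_mv`` over ``rise_ms``
    and back over ``fall_ms``; peaks land exactly on samples.
    """
    n = int(round(duration_s * fs))
    v = np.full(n, baseline_mv)
    n_rise = int(round(rise_ms / 1000.0 * fs))
    n_fall = int(round(fall_ms / 1000.0 * fs))
    for t in spike_times_s:
        p = int(round(t * fs))
        v[p - n_rise : p + 1] = np.linspace(baseline_mv, peak_mv, n_rise + 1)
        v[p : p + n_fall + 1] = np.linspace(peak_mv, baseline_mv, n_fall + 1)
    return v


def spike_family(counts_per_step, currents_pa, fs=FS, pre_s=0.2, step_s=1.0):
    """Step family whose sweeps carry exactly the requested spike counts."""
    sweeps, epochs = [], []
    duration = pre_s + step_s + 0.2
    for count, amp in zip(counts_per_step, currents_pa):
        times = pre_s + (np.arange(count) + 0.5) * (step_s / max(count, 1))
        sweeps.append(triangular_spike_sweep(times, fs=fs, duration_s=duration))
        epochs.append([Epoch(pre_s, step_s, amp)])
    return SweepSet(
        sampling_rate_hz=fs,
        clamp_mode="current_clamp",
        data=np.vstack(sweeps),
        stimulus=epochs,
    )
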
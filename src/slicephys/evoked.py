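"""Optogenetically evoked 10 Hz train analysis.

Trials are averaged point-wise before measurement (averaging first reduces
peak-picking noise bias).  For each pulse the baseline is re-measured over
the 5 ms immediately preceding the light pulse — at 10 Hz the 50 ms
measurement windows leave 50 ms gaps where incomplete decay would otherwise
bias later pulses — and the amplitude is baseline minus the most negative
point of the 50 ms post-pulse window.  The per-pulse area is the trapezoidal
integral of (baseline − signal) over the same window, in pA·ms
(baseline-subtracted).  Short-term dynamics are the per-pulse amplitudes
normalized to the first pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, StructuralError
from .stats import StatResult, compare_groups
from .sweeps import SweepSet

PULSE_BASELINE_S = 0.005
PULSE_WINDOW_S = 0.050


@dataclass(frozen=True)
class TrainMetrics:
    pulse_amplitudes_pA: np.ndarray
    pulse_areas_pA_ms: np.ndarray
    normalized_amplitudes: np.ndarray
    first_pulse_amplitude_pA: float
    n_trials_averaged: int


def train_metrics(sweepset: SweepSet, pulse_times_s: np.ndarray | None = None) -> TrainMetrics:
    """Per-pulse amplitudes, 50 ms areas, and pulse-1-normalized profile.

    Pulse times default to the sweep set's stimulus epochs (the optical
    pulse onsets recorded by the protocol).
    """
    if sweepset.n_sweeps < 1:
        raise StructuralError("need at least one trial")
    if pulse_times_s is None:
        pulse_times_s = np.array([ep.onset_s for ep in sweepset.stimulus[0]])
    pulse_times_s = np.asarray(pulse_times_s, dtype=float)
    if pulse_times_s.size == 0:
        raise StructuralError("no pulse times given and no stimulus epochs present")
    fs = sweepset.sampling_rate_hz
    avg = sweepset.data.mean(axis=0)
    n_base = int(round(PULSE_BASELINE_S * fs))
    n_win = int(round(PULSE_WINDOW_S * fs))
    dt_ms = 1000.0 / fs

    amps = np.empty(pulse_times_s.size)
    areas = np.empty(pulse_times_s.size)
    for i, t_p in enumerate(pulse_times_s):
        p = int(round(t_p * fs))
        if p - n_base < 0 or p + n_win > avg.size:
            raise StructuralError("pulse window outside sweep")
        baseline = float(np.mean(avg[p - n_base : p]))
        seg = avg[p : p + n_win]
        amps[i] = baseline - float(np.min(seg))
        areas[i] = float(np.trapezoid(baseline - seg, dx=dt_ms))
    if amps[0] <= 0:
        raise DegenerateInputError("first-pulse amplitude <= 0: normalization undefined")
    return TrainMetrics(
        pulse_amplitudes_pA=amps,
        pulse_areas_pA_ms=areas,
        normalized_amplitudes=amps / amps[0],
        first_pulse_amplitude_pA=float(amps[0]),
        n_trials_averaged=sweepset.n_sweeps,
    )


def compare_baseline_drug(
    baseline: list[TrainMetrics],
    drug: list[TrainMetrics],
) -> dict:
    """Paired baseline-vs-drug comparison of evoked responses across cells.

    Pairs first-pulse amplitudes per cell, runs a two-tailed paired t test
    on them, and stacks the pulse-1-normalized profiles of both conditions
    for short-term-dynamics comparison.
    """
    if len(baseline) != len(drug) or not baseline:
        raise StructuralError("baseline and drug must pair one TrainMetrics per cell")
    n_pulses = baseline[0].normalized_amplitudes.size
    for tm in list(baseline) + list(drug):
        if tm.normalized_amplitudes.size != n_pulses:
            raise StructuralError("mismatched pulse counts between conditions")
    amps_base = np.array([tm.first_pulse_amplitude_pA for tm in baseline])
    amps_drug = np.array([tm.first_pulse_amplitude_pA for tm in drug])
    result: StatResult = compare_groups(amps_base, amps_drug, design="paired",
                                        measure_class="other")
    return {
        "paired_first_pulse_pA": np.column_stack([amps_base, amps_drug]),
        "normalized_profile_baseline": np.vstack([tm.normalized_amplitudes for tm in baseline]),
        "normalized_profile_drug": np.vstack([tm.normalized_amplitudes for tm in drug]),
        "paired_test": result,
    }
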
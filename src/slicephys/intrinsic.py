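"""Intrinsic-property extraction from current-clamp step families.

Spike detection counts local maxima reaching at least −10 mV.  Threshold is
the point where the voltage slope trajectory (dV/dt, central differences,
mV/ms) reaches 10 mV/ms, located by backward search from the peak for the
last upward crossing — robust to pre-spike wiggle.  Amplitude is peak minus
threshold; half-width is measured at threshold + amplitude/2 with linear
interpolation between samples (20 kHz sampling quantizes at 0.05 ms, so
interpolation removes the quantization bias).

The frequency-current (F-I) analysis regresses spike count on injected
current from the 0 pA step up to the step attaining maximum firing (ties to
the lowest current) or 400 pA, whichever comes first; rheobase is the
smallest step current eliciting at least one spike.  The adaptation index is
computed from the 1 s sweep nearest to twice rheobase as
(N_first_half − N_second_half) / N_total.

Passive properties come from small hyperpolarizing steps: input resistance
from the maximum deflection relative to a 100 ms pre-step baseline, the
membrane time constant from a single-exponential fit between step onset and
the maximum response, capacitance from Cin = TC/Rin, and the sag ratio as
the maximum deflection over the mean deflection of the last 50 ms of the
step (absolute deflections, so sag ≥ 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import StructuralError
from .sweeps import CURRENT_CLAMP, Epoch, SweepSet

MIN_PEAK_MV = -10.0
DVDT_THRESHOLD_MV_PER_MS = 10.0
BASELINE_WINDOW_S = 0.100
SAG_WINDOW_S = 0.050
FI_CURRENT_CAP_PA = 400.0


@dataclass(frozen=True)
class SpikeRecord:
    peak_time_s: float
    peak_mV: float
    threshold_mV: float
    threshold_time_s: float
    amplitude_mV: float
    half_width_ms: float
    max_rise_slope_mV_per_ms: float
    max_decay_slope_mV_per_ms: float


@dataclass(frozen=True)
class FIResult:
    rheobase_pA: float | None
    fi_gain_spikes_per_pA: float
    total_spike_output: int
    max_firing_sweep_pA: float
    currents_pA: np.ndarray
    spike_counts: np.ndarray


@dataclass(frozen=True)
class PassiveProperties:
    rin_MOhm: float
    tc_ms: float | None
    cin_pF: float | None
    sag_ratio: float
    rmp_mV: float


@dataclass(frozen=True)
class IntrinsicProfile:
    rheobase_pA: float | None
    fi_gain_spikes_per_pA: float
    total_spike_output: int
    max_firing_sweep_pA: float
    adaptation_index: float | None
    rin_MOhm: float | None
    tc_ms: float | None
    cin_pF: float | None
    sag_ratio: float | None
    rmp_mV: float | None


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Time at which the segment (t0,v0)→(t1,v1) crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_spikes(
    sweep: np.ndarray,
    sampling_rate_hz: float,
    epoch: Epoch,
    min_peak_mv: float = MIN_PEAK_MV,
    dvdt_threshold: float = DVDT_THRESHOLD_MV_PER_MS,
) -> list[SpikeRecord]:
    """Detect action potentials inside the stimulus epoch of one sweep."""
    sweep = np.asarray(sweep, dtype=np.float64)
    fs = sampling_rate_hz
    i0 = int(round(epoch.onset_s * fs))
    i1 = int(round(epoch.end_s * fs))
    if i0 < 0 or i1 > sweep.size:
        raise StructuralError("stimulus epoch outside sweep")
    dvdt = np.gradient(sweep) * fs / 1000.0  # mV/ms, central differences

    peaks, _ = find_peaks(sweep[i0:i1], height=min_peak_mv)
    peaks = peaks + i0
    records: list[SpikeRecord] = []
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else i0
        # backward search for the last upward crossing of the dV/dt criterion
        thr_idx = None
        for i in range(p - 1, lo - 1, -1):
            if dvdt[i] < dvdt_threshold <= dvdt[i + 1]:
                thr_idx = i + 1
                break
        if thr_idx is None:
            # slope already above criterion back to the search bound
            thr_idx = lo
        thr_v = float(sweep[thr_idx])
        amp = float(sweep[p]) - thr_v
        if amp <= 0:
            continue
        half = thr_v + amp / 2.0

        # rising half-crossing between threshold and peak
        t_rise = None
        for i in range(thr_idx, p):
            if sweep[i] <= half <= sweep[i + 1]:
                t_rise = _interp_crossing(i / fs, (i + 1) / fs, sweep[i], sweep[i + 1], half)
        # falling half-crossing between peak and the post-peak trough
        hi = peaks[k + 1] if k + 1 < len(peaks) else min(i1, p + int(round(0.010 * fs)))
        trough = p + int(np.argmin(sweep[p : max(hi, p + 1)])) if hi > p else p
        t_fall = None
        for i in range(p, trough):
            if sweep[i] >= half >= sweep[i + 1]:
                t_fall = _interp_crossing(i / fs, (i + 1) / fs, sweep[i], sweep[i + 1], half)
                break
        half_width_ms = (t_fall - t_rise) * 1000.0 if (t_rise is not None and t_fall is not None) else float("nan")

        rise_slope = float(np.max(dvdt[thr_idx : p + 1]))
        decay_slope = float(np.min(dvdt[p : trough + 1])) if trough > p else float("nan")
        records.append(
            SpikeRecord(
                peak_time_s=p / fs,
                peak_mV=float(sweep[p]),
                threshold_mV=thr_v,
                threshold_time_s=thr_idx / fs,
                amplitude_mV=amp,
                half_width_ms=half_width_ms,
                max_rise_slope_mV_per_ms=rise_slope,
                max_decay_slope_mV_per_ms=decay_slope,
            )
        )
    return records


def _step_epoch(epochs: list[Epoch]) -> Epoch:
    if not epochs:
        raise StructuralError("sweep has no stimulus epoch")
    return epochs[0]


def fi_analysis(family: SweepSet) -> FIResult:
    """Rheobase, F-I gain, and total spike output of a step family."""
    if family.clamp_mode != CURRENT_CLAMP:
        raise StructuralError("F-I analysis requires current-clamp sweeps")
    currents, counts = [], []
    for i in range(family.n_sweeps):
        ep = _step_epoch(family.stimulus[i])
        currents.append(ep.amplitude)
        counts.append(len(detect_spikes(family.data[i], family.sampling_rate_hz, ep)))
    currents = np.asarray(currents, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.int64)
    order = np.argsort(currents, kind="stable")
    currents, counts = currents[order], counts[order]

    spiking = currents[counts > 0]
    rheobase = float(spiking.min()) if spiking.size else None

    mask = (currents >= 0) & (currents <= FI_CURRENT_CAP_PA)
    cur_fi, cnt_fi = currents[mask], counts[mask]
    if cur_fi.size == 0 or cur_fi[0] != 0.0:
        raise StructuralError("F-I family must include a 0 pA step")
    argmax = int(np.argmax(cnt_fi))  # np.argmax ties break to the lowest current
    max_cur = float(cur_fi[argmax])
    prefix = cur_fi <= max_cur
    if np.count_nonzero(prefix) >= 2:
        gain = float(np.polyfit(cur_fi[prefix], cnt_fi[prefix].astype(float), 1)[0])
    else:
        gain = 0.0
    total = int(cnt_fi[prefix].sum())
    return FIResult(
        rheobase_pA=rheobase,
        fi_gain_spikes_per_pA=gain,
        total_spike_output=total,
        max_firing_sweep_pA=max_cur,
        currents_pA=currents,
        spike_counts=counts,
    )


def adaptation_index(
    family: SweepSet,
    rheobase_pA: float,
    sweep_duration_tol_s: float = 0.1,
) -> float | None:
    """Spike-rate adaptation at approximately twice rheobase.

    Selects the 1 s sweep whose step current is closest to 2× rheobase (ties
    to the lower current) and returns (N_first − N_second)/N_total with
    spikes assigned to halves by peak time; a peak exactly at the midpoint
    counts toward the first half.  Returns None when the selected sweep has
    no spikes.
    """
    target = 2.0 * rheobase_pA
    best = None
    for i in range(family.n_sweeps):
        ep = _step_epoch(family.stimulus[i])
        if abs(ep.duration_s - 1.0) > sweep_duration_tol_s or ep.amplitude <= 0:
            continue
        key = (abs(ep.amplitude - target), ep.amplitude)
        if best is None or key < best[0]:
            best = (key, i, ep)
    if best is None:
        return None
    _, idx, ep = best
    spikes = detect_spikes(family.data[idx], family.sampling_rate_hz, ep)
    if not spikes:
        return None
    mid = ep.onset_s + ep.duration_s / 2.0
    n_first = sum(1 for s in spikes if s.peak_time_s <= mid)
    n_second = len(spikes) - n_first
    return (n_first - n_second) / len(spikes)


def _fit_exponential(t_ms: np.ndarray, v: np.ndarray) -> float | None:
    """Single-exponential least-squares fit; returns tau in ms or None."""
    v0, v_inf = v[0], v[-1]
    dv = v_inf - v0
    if abs(dv) < 1e-9:
        return None
    # initial tau from the 1 − 1/e crossing of the deflection
    frac = (v - v0) / dv
    above = np.nonzero(frac >= 1.0 - 1.0 / np.e)[0]
    tau0 = t_ms[above[0]] if above.size else t_ms[-1] / 3.0
    tau0 = max(tau0, t_ms[1] if t_ms.size > 1 else 1.0)

    def model(t, a, tau, c):
        return c + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t_ms, v, p0=(v0 - v_inf, tau0, v_inf),
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        return None
    return float(popt[1])


def passive_properties(
    family: SweepSet,
    include_tc: bool = True,
) -> PassiveProperties:
    """Passive membrane properties from hyperpolarizing steps.

    Per step: baseline = mean of the 100 ms before the step; the maximum
    response is the extremal deflection from baseline during the step;
    Rin = |ΔV_max / I|; TC from an exponential fit between step onset and the
    time of the maximum response; sag = |ΔV_max| / |mean ΔV of the last
    50 ms|.  Values are averaged over all hyperpolarizing steps and
    Cin = TC/Rin is computed from the averaged values (exact identity on the
    stored numbers).
    """
    fs = family.sampling_rate_hz
    rins, tcs, sags, rmps = [], [], [], []
    for i in range(family.n_sweeps):
        ep = _step_epoch(family.stimulus[i])
        if ep.amplitude >= 0:
            continue
        i_on = int(round(ep.onset_s * fs))
        i_off = int(round(ep.end_s * fs))
        n_base = int(round(BASELINE_WINDOW_S * fs))
        if i_on < n_base:
            raise StructuralError("need >= 100 ms pre-stimulus baseline")
        v = family.data[i]
        baseline = float(np.mean(v[i_on - n_base : i_on]))
        rmps.append(baseline)
        dev = v[i_on:i_off] - baseline
        idx_max = int(np.argmax(np.abs(dev)))
        dv_max = float(dev[idx_max])
        rins.append(abs(dv_max / ep.amplitude) * 1000.0)  # mV/pA -> MOhm
        n_sag = int(round(SAG_WINDOW_S * fs))
        ss_mean = float(np.mean(dev[-n_sag:]))
        sags.append(abs(dv_max) / abs(ss_mean) if ss_mean != 0 else float("nan"))
        if include_tc and idx_max >= 5:
            t_ms = np.arange(idx_max + 1) / fs * 1000.0
            tau = _fit_exponential(t_ms, v[i_on : i_on + idx_max + 1])
            if tau is not None:
                tcs.append(tau)
    if not rins:
        raise StructuralError("no hyperpolarizing steps in family")
    rin = float(np.mean(rins))
    tc = float(np.mean(tcs)) if tcs else None
    cin = 1000.0 * tc / rin if tc is not None else None  # ms/MOhm -> pF
    return PassiveProperties(
        rin_MOhm=rin,
        tc_ms=tc,
        cin_pF=cin,
        sag_ratio=float(np.nanmean(sags)),
        rmp_mV=float(np.mean(rmps)),
    )


def intrinsic_profile(family: SweepSet) -> IntrinsicProfile:
    """Full per-cell intrinsic profile from one step family containing both
    hyperpolarizing and depolarizing steps."""
    fi = fi_analysis(family)
    adapt = adaptation_index(family, fi.rheobase_pA) if fi.rheobase_pA is not None else None
    has_hyp = any(
        eps and eps[0].amplitude < 0 for eps in family.stimulus
    )
    if has_hyp:
        passive = passive_properties(family)
        rin, tc, cin, sag, rmp = (passive.rin_MOhm, passive.tc_ms, passive.cin_pF,
                                  passive.sag_ratio, passive.rmp_mV)
    else:
        rin = tc = cin = sag = rmp = None
    return IntrinsicProfile(
        rheobase_pA=fi.rheobase_pA,
        fi_gain_spikes_per_pA=fi.fi_gain_spikes_per_pA,
        total_spike_output=fi.total_spike_output,
        max_firing_sweep_pA=fi.max_firing_sweep_pA,
        adaptation_index=adapt,
        rin_MOhm=rin,
        tc_ms=tc,
        cin_pF=cin,
        sag_ratio=sag,
        rmp_mV=rmp,
    )
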
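"""Ground-truth simulators for every downstream analysis stage.

Raw recordings for this kind of slice-physiology study are rarely deposited,
so every detector and feature extractor in the package is validated against
synthetic data with known ground truth:

* ``simulate_current_clamp`` — an adaptive exponential integrate-and-fire
  (AdEx) membrane with an additive slow, hyperpolarization-activated sag
  current.  AdEx is a stand-in for the real neurons: it reproduces every
  feature the intrinsic-property extractor measures (threshold upswing,
  spike-frequency adaptation, sag, passive RC response) with interpretable
  parameters.
* ``simulate_voltage_clamp`` — 30 s voltage-clamp sweeps at −70 mV with a
  −5 mV/250 ms test pulse, homogeneous-Poisson negative-going biexponential
  synaptic events of lognormal amplitude, Gaussian noise, and an optional
  slow sinusoidal baseline drift.
* ``simulate_evoked_train`` — 10 Hz optogenetic trains whose per-pulse true
  amplitudes follow the Tsodyks–Markram resource/utilization recurrence.
* ``generate_cell_table`` — negative-binomial cell×gene count tables with
  Allen-style region and cluster annotations.

All generators are bit-reproducible given (params, seed).  Event kernels are
peak-normalized (max |kernel| = 1 on the sampling grid) so configured
amplitudes are trace amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import SimulationError, StructuralError
from .sweeps import CURRENT_CLAMP, VOLTAGE_CLAMP, Epoch, SweepSet

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronParams:
    """AdEx + sag membrane parameters.

    ``sag_strength`` is the sag conductance expressed as a fraction of the
    leak conductance (0 disables sag); ``delta_t_mv <= 0`` disables the
    spike-initiation term, leaving a passive (leaky) membrane.
    """

    r_mohm: float = 150.0
    c_pf: float = 100.0
    e_l_mv: float = -65.0
    delta_t_mv: float = 2.0
    v_t_mv: float = -45.0
    a_ns: float = 0.0
    b_pa: float = 30.0
    tau_w_ms: float = 120.0
    sag_strength: float = 0.0
    sag_tau_ms: float = 50.0
    refractory_ms: float = 2.0
    v_reset_mv: float = -58.0
    spike_cut_mv: float = 0.0
    v_peak_mv: float = 35.0

    @property
    def tau_m_ms(self) -> float:
        return self.r_mohm * self.c_pf / 1000.0


@dataclass(frozen=True)
class CCProtocol:
    """Current-clamp step family: bias to −65 mV, −20 pA passive step plus
    0–400 pA suprathreshold family in 50 pA increments."""

    sampling_rate_hz: float = 20_000.0
    pre_s: float = 0.2
    step_s: float = 1.0
    post_s: float = 0.3
    amplitudes_pa: tuple[float, ...] = (-20.0, 0.0, 50.0, 100.0, 150.0, 200.0,
                                        250.0, 300.0, 350.0, 400.0)
    bias_mv: float = -65.0


@dataclass(frozen=True)
class EventGenParams:
    """Poisson sEPSC generator parameters; amplitudes are lognormal in pA."""

    rate_hz: float = 2.0
    amp_mu_log: float = math.log(18.0)
    amp_sigma_log: float = 0.35
    rise_tau_ms: float = 0.5
    decay_tau_ms: float = 8.0
    noise_sd_pa: float = 2.0
    drift_amp_pa: float = 0.0
    drift_period_s: float = 5.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or not math.isfinite(self.rate_hz):
            raise StructuralError("rate_hz must be finite and >= 0")
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise StructuralError("need decay_tau > rise_tau > 0")
        if self.amp_sigma_log < 0:
            raise StructuralError("amp_sigma_log must be >= 0")


@dataclass(frozen=True)
class VCProtocol:
    """Spontaneous-activity protocol: 30 s sweeps at −70 mV with a
    −5 mV/250 ms test pulse near the sweep start."""

    n_sweeps: int = 10
    sweep_s: float = 30.0
    sampling_rate_hz: float = 20_000.0
    holding_mv: float = -70.0
    test_pulse: Epoch = field(default_factory=lambda: Epoch(0.1, 0.25, -5.0))
    # fixed RC model behind the test pulse
    tp_rs_mohm: float = 15.0
    tp_rm_mohm: float = 150.0
    tp_cm_pf: float = 100.0


@dataclass(frozen=True)
class STPParams:
    """Tsodyks–Markram evoked-train parameters.

    ``a1_pa`` is the first-pulse amplitude; ``u`` the baseline release
    fraction; resources recover with ``tau_rec_s``; utilization decays with
    ``tau_facil_s`` (0 disables facilitation).
    """

    a1_pa: float = 100.0
    u: float = 0.5
    tau_rec_s: float = 0.5
    tau_facil_s: float = 0.0
    n_pulses: int = 10
    rate_hz: float = 10.0
    rise_tau_ms: float = 0.5
    decay_tau_ms: float = 8.0
    noise_sd_pa: float = 0.0
    n_trials: int = 5
    pre_s: float = 0.5
    post_s: float = 0.5
    sampling_rate_hz: float = 20_000.0

    def __post_init__(self) -> None:
        if not (0 < self.u <= 1):
            raise StructuralError("release fraction u must be in (0, 1]")
        if self.tau_rec_s <= 0 or self.tau_facil_s < 0:
            raise StructuralError("tau_rec must be > 0 and tau_facil >= 0")
        if self.n_pulses < 1:
            raise StructuralError("n_pulses must be >= 1")


@dataclass(frozen=True)
class CellGroup:
    """One group of cells in a synthetic annotated expression table."""

    region_label: str
    cluster_label: str
    mean_count: float
    dispersion: float = 2.0
    n_cells: int = 100
    cell_class: str = "glutamatergic"

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise StructuralError("mean_count must be >= 0")
        if self.dispersion <= 0:
            raise StructuralError("dispersion must be > 0")


@dataclass(frozen=True)
class CurrentClampTruth:
    params: NeuronParams
    spike_times_s: list[np.ndarray]
    bias_current_pa: float


@dataclass(frozen=True)
class EventTruth:
    params: EventGenParams
    event_times_s: list[np.ndarray]
    event_amps_pa: list[np.ndarray]


@dataclass(frozen=True)
class TrainTruth:
    params: STPParams
    pulse_times_s: np.ndarray
    pulse_amps_pa: np.ndarray
    normalized: np.ndarray


# ---------------------------------------------------------------------------
# AdEx + sag integrator
# ---------------------------------------------------------------------------


@njit(cache=False)
def _integrate_adex(
    i_stim, dt_ms, oversample,
    g_l, c_pf, e_l, delta_t, v_t, a_ns, b_pa, tau_w,
    g_h, e_h, m_vhalf, m_k, sag_tau,
    v_reset, spike_cut, v_peak, refr_steps, v0,
):  # pragma: no cover - exercised via simulate_current_clamp
    n = i_stim.shape[0]
    v_out = np.empty(n)
    spikes = []
    dt_f = dt_ms / oversample
    v = v0
    w = a_ns * (v - e_l)
    m = 1.0 / (1.0 + math.exp((v - m_vhalf) / m_k))
    decay_w = math.exp(-dt_f / tau_w)
    decay_m = math.exp(-dt_f / sag_tau)
    refr = 0
    for j in range(n):
        spiked = False
        for _ in range(oversample):
            m_inf = 1.0 / (1.0 + math.exp((v - m_vhalf) / m_k))
            m = m_inf + (m - m_inf) * decay_m
            if refr > 0:
                refr -= 1
                v = v_reset
                w_inf = a_ns * (v - e_l)
                w = w_inf + (w - w_inf) * decay_w
                continue
            if delta_t > 0:
                arg = (v - v_t) / delta_t
                if arg > 30.0:
                    arg = 30.0
                i_exp = g_l * delta_t * math.exp(arg)
            else:
                i_exp = 0.0
            g_tot = g_l + g_h * m
            v_inf = (g_l * e_l + g_h * m * e_h + i_exp - w + i_stim[j]) / g_tot
            v = v_inf + (v - v_inf) * math.exp(-dt_f * g_tot / c_pf)
            w_inf = a_ns * (v - e_l)
            w = w_inf + (w - w_inf) * decay_w
            if v >= spike_cut:
                spiked = True
                v = v_reset
                w += b_pa
                refr = refr_steps
        v_out[j] = v_peak if spiked else v
        if spiked:
            spikes.append(j)
    return v_out, np.array(spikes, dtype=np.int64)


SAG_E_MV = -45.0
SAG_VHALF_MV = -80.0
SAG_K_MV = 6.0


def bias_current_pa(params: NeuronParams, bias_mv: float) -> float:
    """Holding current that rests the membrane at ``bias_mv`` (steady state,
    sag activation at its equilibrium value)."""
    g_l = 1000.0 / params.r_mohm
    g_h = params.sag_strength * g_l
    m_inf = 1.0 / (1.0 + math.exp((bias_mv - SAG_VHALF_MV) / SAG_K_MV))
    # leak + sag + adaptation must sum to zero at rest
    w_rest = params.a_ns * (bias_mv - params.e_l_mv)
    return -(g_l * (params.e_l_mv - bias_mv) + g_h * m_inf * (SAG_E_MV - bias_mv) - w_rest)


def simulate_current_clamp(
    params: NeuronParams,
    protocol: CCProtocol | None = None,
    seed: int | None = None,
    noise_sd_mv: float = 0.0,
    oversample: int = 1,
) -> tuple[SweepSet, CurrentClampTruth]:
    """Integrate a current-clamp step family; returns sweeps plus true spike
    times per sweep.

    Integration is fixed-step exponential Euler at the trace sampling
    interval; ``oversample > 1`` integrates on a finer grid (reference
    integrator for convergence checks) while emitting samples at the native
    rate.  Deterministic given ``seed`` (``noise_sd_mv`` is observation
    noise added to the emitted trace only).
    """
    protocol = protocol or CCProtocol()
    fs = protocol.sampling_rate_hz
    dt_ms = 1000.0 / fs
    n_pre = int(round(protocol.pre_s * fs))
    n_step = int(round(protocol.step_s * fs))
    n_post = int(round(protocol.post_s * fs))
    n = n_pre + n_step + n_post
    g_l = 1000.0 / params.r_mohm
    g_h = params.sag_strength * g_l
    i_bias = bias_current_pa(params, protocol.bias_mv)
    refr_steps = int(round(params.refractory_ms / (dt_ms / oversample)))
    rng = np.random.default_rng(seed)

    sweeps, truth_spikes, epochs = [], [], []
    for amp in protocol.amplitudes_pa:
        i_stim = np.full(n, i_bias)
        i_stim[n_pre : n_pre + n_step] += amp
        v, spk = _integrate_adex(
            i_stim, dt_ms, oversample,
            g_l, params.c_pf, params.e_l_mv, params.delta_t_mv, params.v_t_mv,
            params.a_ns, params.b_pa, params.tau_w_ms,
            g_h, SAG_E_MV, SAG_VHALF_MV, SAG_K_MV, params.sag_tau_ms,
            params.v_reset_mv, params.spike_cut_mv, params.v_peak_mv,
            refr_steps, protocol.bias_mv,
        )
        if not np.all(np.isfinite(v)):
            raise SimulationError(f"non-finite membrane state at step {amp} pA")
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, size=n)
        sweeps.append(v)
        truth_spikes.append(spk / fs)
        epochs.append([Epoch(protocol.pre_s, protocol.step_s, amp)])

    ss = SweepSet(
        sampling_rate_hz=fs,
        clamp_mode=CURRENT_CLAMP,
        data=np.vstack(sweeps),
        stimulus=epochs,
        holding_mv=protocol.bias_mv,
        annotations={"protocol": "current_clamp_steps"},
    )
    return ss, CurrentClampTruth(params=params, spike_times_s=truth_spikes,
                                 bias_current_pa=i_bias)


# ---------------------------------------------------------------------------
# synaptic kernels and voltage-clamp sweeps
# ---------------------------------------------------------------------------


def psc_kernel(rise_tau_ms: float, decay_tau_ms: float, fs: float) -> np.ndarray:
    """Biexponential synaptic kernel, peak-normalized to 1 on the sampling
    grid, truncated at 8 decay time constants."""
    n = int(round((rise_tau_ms + 8.0 * decay_tau_ms) / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms
    k = np.exp(-t / decay_tau_ms) - np.exp(-t / rise_tau_ms)
    return k / k.max()


def _test_pulse_current(protocol: VCProtocol, n: int) -> np.ndarray:
    """Analytic pipette current of the fixed RC model for the −5 mV pulse."""
    fs = protocol.sampling_rate_hz
    rs, rm, cm = protocol.tp_rs_mohm, protocol.tp_rm_mohm, protocol.tp_cm_pf
    tau_ms = cm * (rs * rm / (rs + rm)) / 1000.0
    dv = protocol.test_pulse.amplitude  # mV, signed
    i_ss = dv / (rs + rm) * 1000.0  # pA
    i_peak = dv / rs * 1000.0
    out = np.zeros(n)
    i_on = int(round(protocol.test_pulse.onset_s * fs))
    i_off = int(round(protocol.test_pulse.end_s * fs))
    t_on = np.arange(i_off - i_on) / fs * 1000.0
    out[i_on:i_off] = i_ss + (i_peak - i_ss) * np.exp(-t_on / tau_ms)
    t_off = np.arange(min(n - i_off, int(round(10 * tau_ms / 1000.0 * fs)))) / fs * 1000.0
    out[i_off : i_off + t_off.size] = -(i_peak - i_ss) * np.exp(-t_off / tau_ms)
    return out


def simulate_voltage_clamp(
    params: EventGenParams,
    protocol: VCProtocol | None = None,
    seed: int | None = None,
) -> tuple[SweepSet, EventTruth]:
    """Generate voltage-clamp sweeps carrying Poisson-timed sEPSCs.

    Event onsets are homogeneous Poisson over the whole sweep; each event
    adds a negative-going peak-normalized biexponential of lognormal
    amplitude (linear superposition, so overlapping events summate).
    Gaussian noise and an optional sinusoidal drift are added on top of the
    analytic test-pulse current.  Ground truth records every event onset and
    amplitude.
    """
    protocol = protocol or VCProtocol()
    fs = protocol.sampling_rate_hz
    n = int(round(protocol.sweep_s * fs))
    rng = np.random.default_rng(seed)
    kernel = psc_kernel(params.rise_tau_ms, params.decay_tau_ms, fs)
    tp = _test_pulse_current(protocol, n)
    t = np.arange(n) / fs
    drift = (
        params.drift_amp_pa * np.sin(2 * np.pi * t / params.drift_period_s)
        if params.drift_amp_pa > 0
        else 0.0
    )

    sweeps, times_all, amps_all = [], [], []
    for _ in range(protocol.n_sweeps):
        n_ev = rng.poisson(params.rate_hz * protocol.sweep_s)
        times = np.sort(rng.uniform(0.0, protocol.sweep_s, size=n_ev))
        amps = rng.lognormal(params.amp_mu_log, params.amp_sigma_log, size=n_ev)
        trace = tp.copy()
        for t_ev, a_ev in zip(times, amps):
            i0 = int(round(t_ev * fs))
            seg = min(kernel.size, n - i0)
            trace[i0 : i0 + seg] -= a_ev * kernel[:seg]
        if params.noise_sd_pa > 0:
            trace += rng.normal(0.0, params.noise_sd_pa, size=n)
        trace = trace + drift
        sweeps.append(trace)
        times_all.append(times)
        amps_all.append(amps)

    ss = SweepSet(
        sampling_rate_hz=fs,
        clamp_mode=VOLTAGE_CLAMP,
        data=np.vstack(sweeps),
        stimulus=[[protocol.test_pulse] for _ in range(protocol.n_sweeps)],
        holding_mv=protocol.holding_mv,
        annotations={"protocol": "spontaneous_epsc"},
    )
    return ss, EventTruth(params=params, event_times_s=times_all, event_amps_pa=amps_all)


# ---------------------------------------------------------------------------
# Tsodyks–Markram evoked trains
# ---------------------------------------------------------------------------


def tm_release(u: float, tau_rec_s: float, tau_facil_s: float,
               n_pulses: int, dt_s: float) -> np.ndarray:
    """Per-pulse release u_n·x_n of the Tsodyks–Markram recurrence.

    Resources x (x_1 = 1) are consumed by the fraction u_n·x_n at each pulse
    and recover toward 1 with ``tau_rec_s``; utilization u (u_1 = u) jumps by
    u·(1 − u_n) at each pulse and decays back with ``tau_facil_s`` (0 means
    no facilitation: u_n = u for all pulses).
    """
    rel = np.empty(n_pulses)
    un, xn = u, 1.0
    f = math.exp(-dt_s / tau_facil_s) if tau_facil_s > 0 else 0.0
    d = math.exp(-dt_s / tau_rec_s)
    for i in range(n_pulses):
        rel[i] = un * xn
        xn = 1.0 - (1.0 - xn * (1.0 - un)) * d
        un = u + un * (1.0 - u) * f
    return rel


def simulate_evoked_train(
    params: STPParams,
    seed: int | None = None,
) -> tuple[SweepSet, TrainTruth]:
    """Generate evoked-train trials with Tsodyks–Markram per-pulse amplitudes
    convolved with the synaptic kernel at the stimulation interval."""
    fs = params.sampling_rate_hz
    dt_s = 1.0 / params.rate_hz
    pulse_times = params.pre_s + np.arange(params.n_pulses) * dt_s
    duration = params.pre_s + (params.n_pulses - 1) * dt_s + 0.05 + params.post_s
    n = int(round(duration * fs))
    rel = tm_release(params.u, params.tau_rec_s, params.tau_facil_s,
                     params.n_pulses, dt_s)
    amps = params.a1_pa * rel / rel[0]
    kernel = psc_kernel(params.rise_tau_ms, params.decay_tau_ms, fs)
    rng = np.random.default_rng(seed)

    clean = np.zeros(n)
    for t_p, a_p in zip(pulse_times, amps):
        i0 = int(round(t_p * fs))
        seg = min(kernel.size, n - i0)
        clean[i0 : i0 + seg] -= a_p * kernel[:seg]
    trials = []
    for _ in range(params.n_trials):
        tr = clean.copy()
        if params.noise_sd_pa > 0:
            tr += rng.normal(0.0, params.noise_sd_pa, size=n)
        trials.append(tr)

    epochs = [Epoch(t_p, 0.001, 1.0) for t_p in pulse_times]
    ss = SweepSet(
        sampling_rate_hz=fs,
        clamp_mode=VOLTAGE_CLAMP,
        data=np.vstack(trials),
        stimulus=[list(epochs) for _ in range(params.n_trials)],
        holding_mv=-70.0,
        annotations={"protocol": "evoked_train", "opto": "true"},
    )
    return ss, TrainTruth(params=params, pulse_times_s=pulse_times,
                          pulse_amps_pa=amps, normalized=amps / amps[0])


# ---------------------------------------------------------------------------
# annotated expression tables
# ---------------------------------------------------------------------------


def generate_cell_table(groups: list[CellGroup], seed: int | None = None) -> pd.DataFrame:
    """Negative-binomial cell×gene counts with region/cluster annotations.

    Counts for a group with mean m and dispersion θ are NB(θ, θ/(θ+m)); a
    zero mean yields all-zero counts.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for g in groups:
        if g.mean_count == 0:
            counts = np.zeros(g.n_cells, dtype=np.int64)
        else:
            p = g.dispersion / (g.dispersion + g.mean_count)
            counts = rng.negative_binomial(g.dispersion, p, size=g.n_cells)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"cell_{offset + i:06d}" for i in range(g.n_cells)],
                    "region_label": g.region_label,
                    "cluster_label": g.cluster_label,
                    "cell_class": g.cell_class,
                    "target_gene_count": counts,
                }
            )
        )
        offset += g.n_cells
    return pd.concat(frames, ignore_index=True)
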
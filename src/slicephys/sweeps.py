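"""Sweep data model, file round-trip, and voltage-clamp test-pulse metrics.

A recording is a :class:`SweepSet`: an ordered stack of equally long,
uniformly sampled sweeps with protocol metadata.  Current-clamp sweeps hold
membrane potential in mV; voltage-clamp sweeps hold pipette current in pA
(inward currents negative, as recorded).  All windows are specified in
seconds so that sampling rates other than the 20 kHz used for fixtures are
accepted transparently.

Two on-disk dialects are supported:

* a text dialect — one CSV per sweep set (columns ``sweep,time_s,value``)
  with a JSON sidecar carrying sampling rate, clamp mode, stimulus epochs,
  holding level and free-form annotations; values are written with 17
  significant digits so the round-trip is bit-exact;
* an HDF5 dialect — a single ``sweeps`` dataset plus attributes, for large
  synthetic recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import DegenerateInputError, FormatError, StructuralError

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass(frozen=True)
class Epoch:
    """A stimulus epoch: onset and duration in seconds, amplitude in the
    command units of the clamp mode (pA in current clamp, mV in voltage
    clamp)."""

    onset_s: float
    duration_s: float
    amplitude: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SweepSet:
    """An ordered set of uniformly sampled sweeps with protocol metadata."""

    sampling_rate_hz: float
    clamp_mode: str
    data: np.ndarray  # (n_sweeps, n_samples) float64
    stimulus: list[list[Epoch]] = field(default_factory=list)
    holding_mv: float = float("nan")
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise StructuralError("sweep data must be a 2-D (n_sweeps, n_samples) array")
        if self.sampling_rate_hz <= 0:
            raise StructuralError("sampling_rate_hz must be > 0")
        if self.clamp_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise FormatError(f"unknown clamp mode {self.clamp_mode!r}")
        if not self.stimulus:
            self.stimulus = [[] for _ in range(self.n_sweeps)]
        if len(self.stimulus) != self.n_sweeps:
            raise StructuralError("stimulus epoch lists must match the number of sweeps")
        for epochs in self.stimulus:
            for ep in epochs:
                if ep.onset_s < 0 or ep.end_s > self.duration_s + 1e-12:
                    raise StructuralError(
                        f"epoch [{ep.onset_s}, {ep.end_s}] s outside sweep of "
                        f"{self.duration_s} s"
                    )

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def sample_index(self, t_s: float) -> int:
        """Nearest-floor sample index of a time point."""
        return int(round(t_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class TestPulseMetrics:
    """Series/input resistance and currents measured from a voltage-clamp
    test pulse.

    ``holding_current_pA`` is the mean current over the 100 ms pre-pulse
    baseline; ``baseline_current_pA`` is the absolute mean current over the
    final 50 ms of the pulse (the steady-state plateau).
    """

    series_resistance_MOhm: float
    input_resistance_MOhm: float
    holding_current_pA: float
    baseline_current_pA: float


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------


def _epochs_to_json(stimulus: list[list[Epoch]]) -> list[list[dict]]:
    return [
        [{"onset_s": e.onset_s, "duration_s": e.duration_s, "amplitude": e.amplitude} for e in eps]
        for eps in stimulus
    ]


def _epochs_from_json(obj: list[list[dict]]) -> list[list[Epoch]]:
    return [[Epoch(e["onset_s"], e["duration_s"], e["amplitude"]) for e in eps] for eps in obj]


def save_sweepset(sweepset: SweepSet, path: str | Path) -> None:
    """Write a sweep set; dialect chosen by extension (``.csv`` or ``.h5``)."""
    path = Path(path)
    if path.suffix == ".csv":
        _save_csv(sweepset, path)
    elif path.suffix in (".h5", ".hdf5"):
        _save_hdf5(sweepset, path)
    else:
        raise FormatError(f"unknown sweep-file extension {path.suffix!r}")


def load_sweepset(path: str | Path) -> SweepSet:
    """Read a sweep set; dialect chosen by extension (``.csv`` or ``.h5``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".csv":
        return _load_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_hdf5(path)
    raise FormatError(f"unknown sweep-file extension {path.suffix!r}")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def _save_csv(ss: SweepSet, path: Path) -> None:
    dt = 1.0 / ss.sampling_rate_hz
    with open(path, "w") as fh:
        fh.write("sweep,time_s,value\n")
        for i in range(ss.n_sweeps):
            for j in range(ss.n_samples):
                fh.write(f"{i},{j * dt:.17g},{ss.data[i, j]:.17g}\n")
    meta = {
        "sampling_rate_hz": ss.sampling_rate_hz,
        "clamp_mode": ss.clamp_mode,
        "holding_mv": None if np.isnan(ss.holding_mv) else ss.holding_mv,
        "epochs": _epochs_to_json(ss.stimulus),
        "annotations": ss.annotations,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _load_csv(path: Path) -> SweepSet:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("sampling_rate_hz", "clamp_mode"):
        if key not in meta:
            raise FormatError(f"sidecar missing required key {key!r}")
    sweep_ids: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "sweep,time_s,value":
            raise FormatError(f"unexpected CSV header {header!r}")
        for line in fh:
            s, _, v = line.rstrip("\n").split(",")
            sweep_ids.append(int(s))
            values.append(float(v))
    ids = np.asarray(sweep_ids)
    vals = np.asarray(values)
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) == 0:
        raise StructuralError("empty sweep file")
    if len(set(counts)) != 1:
        raise StructuralError(f"ragged sweeps: per-sweep sample counts {dict(zip(uniq, counts))}")
    data = vals.reshape(len(uniq), counts[0])
    holding = meta.get("holding_mv")
    return SweepSet(
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        clamp_mode=meta["clamp_mode"],
        data=data,
        stimulus=_epochs_from_json(meta.get("epochs", [])),
        holding_mv=float("nan") if holding is None else float(holding),
        annotations=dict(meta.get("annotations", {})),
    )


def _save_hdf5(ss: SweepSet, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("sweeps", data=ss.data)
        dset.attrs["sampling_rate_hz"] = ss.sampling_rate_hz
        dset.attrs["clamp_mode"] = ss.clamp_mode
        dset.attrs["holding_mv"] = ss.holding_mv
        dset.attrs["epochs_json"] = json.dumps(_epochs_to_json(ss.stimulus))
        dset.attrs["annotations_json"] = json.dumps(ss.annotations)


def _load_hdf5(path: Path) -> SweepSet:
    with h5py.File(path, "r") as fh:
        if "sweeps" not in fh:
            raise FormatError("HDF5 file lacks a 'sweeps' dataset")
        dset = fh["sweeps"]
        for key in ("sampling_rate_hz", "clamp_mode"):
            if key not in dset.attrs:
                raise FormatError(f"HDF5 sweeps dataset missing attribute {key!r}")
        return SweepSet(
            sampling_rate_hz=float(dset.attrs["sampling_rate_hz"]),
            clamp_mode=str(dset.attrs["clamp_mode"]),
            data=dset[()],
            stimulus=_epochs_from_json(json.loads(dset.attrs.get("epochs_json", "[]"))),
            holding_mv=float(dset.attrs.get("holding_mv", float("nan"))),
            annotations=json.loads(dset.attrs.get("annotations_json", "{}")),
        )


# ---------------------------------------------------------------------------
# test-pulse metrics
# ---------------------------------------------------------------------------

BASELINE_WINDOW_S = 0.100  # pre-pulse baseline
STEADY_STATE_WINDOW_S = 0.050  # plateau at the end of the pulse


def test_pulse_metrics(
    sweep: np.ndarray,
    pulse: Epoch,
    sampling_rate_hz: float,
) -> TestPulseMetrics:
    """Series and input resistance from a voltage-clamp test pulse.

    The pipette picks up a capacitive transient whose peak current is limited
    only by the access (series) resistance, so ``Rs = ΔV / I_peak``.  The
    steady-state plateau sees the series and membrane resistances in series,
    so ``Rin = ΔV / I_ss − Rs``.  Both deviations are measured relative to a
    100 ms pre-pulse baseline; the steady state is the mean of the final
    50 ms of the pulse.  With ΔV in mV and currents in pA, resistances come
    out in GΩ and are converted to MΩ.
    """
    sweep = np.asarray(sweep, dtype=np.float64)
    dv_mv = abs(pulse.amplitude)
    if dv_mv == 0:
        raise DegenerateInputError("zero-amplitude test pulse")
    fs = sampling_rate_hz
    i_on = int(round(pulse.onset_s * fs))
    i_off = int(round(pulse.end_s * fs))
    if i_on <= 0 or i_off > sweep.size:
        raise StructuralError("test-pulse epoch outside sweep")
    i_base = max(0, i_on - int(round(BASELINE_WINDOW_S * fs)))
    baseline = float(np.mean(sweep[i_base:i_on]))
    dev = sweep[i_on:i_off] - baseline
    peak = float(dev[np.argmax(np.abs(dev))])
    n_ss = int(round(STEADY_STATE_WINDOW_S * fs))
    i_ss = float(np.mean(dev[-n_ss:]))
    if abs(peak) < 1e-12 or abs(i_ss) < 1e-12:
        raise DegenerateInputError("flat trace: no detectable test-pulse response")
    rs_mohm = 1000.0 * dv_mv / abs(peak)
    total_mohm = 1000.0 * dv_mv / abs(i_ss)
    return TestPulseMetrics(
        series_resistance_MOhm=rs_mohm,
        input_resistance_MOhm=total_mohm - rs_mohm,
        holding_current_pA=baseline,
        baseline_current_pA=float(np.mean(sweep[i_off - n_ss : i_off])),
    )


def series_stability(first: TestPulseMetrics, last: TestPulseMetrics) -> tuple[float, float]:
    """Fractional change of Rs and Rin between the first and last sweep.

    Returns ``(rs_change_frac, rin_change_frac)`` computed as
    ``(last − first) / first``; monitoring uses endpoint sweeps.
    """
    rs_change = (last.series_resistance_MOhm - first.series_resistance_MOhm) / (
        first.series_resistance_MOhm
    )
    rin_change = (last.input_resistance_MOhm - first.input_resistance_MOhm) / (
        first.input_resistance_MOhm
    )
    return rs_change, rin_change
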
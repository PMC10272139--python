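"""Current-clamp (patch) analysis.

Extracts the intrinsic-excitability panel from step-current sweep sets:
resting membrane potential, input resistance (slope of the I–V plot),
rheobase, F–I curve and its slope, action-potential waveform features
(threshold at the peak of the second voltage derivative during the rise,
amplitude, FWHM, max/min dV/dt), medium afterhyperpolarization after a
spike train, and the tonic-current baseline shift after drug application.

Voltages are mV, currents pA, times s; dV/dt is mV/ms.  Resistance from a
slope in mV/pA is GΩ, reported in MΩ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .trace import Trace, Unit

__all__ = [
    "StepProtocol",
    "Sweep",
    "SweepSet",
    "ApFeatures",
    "ExcitabilitySummary",
    "resting_membrane_potential",
    "input_resistance",
    "detect_aps",
    "ap_waveform_features",
    "fi_curve",
    "rheobase",
    "mahp_amplitude",
    "tonic_current_shift",
    "read_sweeps",
    "write_sweeps",
]


@dataclass(frozen=True)
class StepProtocol:
    """Timing and current ladder of a step protocol."""

    step_start_s: float
    step_end_s: float
    currents_pa: tuple[float, ...]
    baseline_window_ms: float = 100.0

    def __post_init__(self) -> None:
        if not self.step_end_s > self.step_start_s:
            raise ValueError("step_end_s must exceed step_start_s")
        c = np.asarray(self.currents_pa, dtype=float)
        if c.size and not (np.all(np.diff(c) > 0) or np.all(np.diff(c) < 0)):
            raise ValueError("currents_pa must be strictly monotone")
        object.__setattr__(self, "currents_pa", tuple(float(v) for v in c))


@dataclass(frozen=True)
class Sweep:
    trace: Trace
    current_pa: float


@dataclass(frozen=True)
class SweepSet:
    sweeps: tuple[Sweep, ...]
    protocol: StepProtocol

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", tuple(self.sweeps))

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


@dataclass(frozen=True)
class ApFeatures:
    """Waveform features of one action potential."""

    threshold_mv: float
    amplitude_mv: float
    fwhm_ms: float
    max_dvdt_mv_per_ms: float
    min_dvdt_mv_per_ms: float
    peak_mv: float
    peak_time_s: float


@dataclass(frozen=True)
class ExcitabilitySummary:
    rmp_mv: Optional[float]
    input_resistance_mohm: Optional[float]
    rheobase_pa: Optional[float]
    fi_counts: dict[float, int]
    fi_slope: Optional[float]
    mahp_mv: Optional[float]


def resting_membrane_potential(trace: Trace, window_ms: float = 100.0) -> float:
    """Mean membrane potential over the first ``window_ms`` of the trace."""
    n = int(round(window_ms / 1000.0 * trace.fs))
    if n < 1 or n > len(trace):
        raise ValueError(f"window of {window_ms} ms does not fit a {trace.duration_s}s trace")
    return float(np.mean(trace.samples[:n]))


def _dvdt(v: np.ndarray, fs: float) -> np.ndarray:
    """First differences of voltage over time, mV/ms; length len(v) - 1."""
    return np.diff(v) * fs / 1000.0


def detect_aps(
    trace: Trace,
    dvdt_threshold_mv_per_ms: float = 10.0,
    min_peak_mv: float = -10.0,
) -> np.ndarray:
    """Indices of action-potential peaks.

    An AP is a contiguous excursion of V above ``min_peak_mv`` whose rise
    reaches ``dvdt_threshold_mv_per_ms``; one detection per excursion, at
    the voltage maximum.  Returns an empty array for subthreshold traces.
    """
    v = trace.samples
    dv = _dvdt(v, trace.fs)
    above = v > min_peak_mv
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    pre = max(1, int(round(0.002 * trace.fs)))  # look 2 ms before excursion onset
    peaks = []
    for a, b in zip(starts, stops):
        lo = max(0, a - pre)
        rise = dv[lo : max(lo + 1, b - 1)]
        if rise.size and rise.max() >= dvdt_threshold_mv_per_ms:
            peaks.append(a + int(np.argmax(v[a:b])))
    return np.asarray(peaks, dtype=int)


def ap_waveform_features(
    trace: Trace,
    peak_index: int,
    dvdt_threshold_mv_per_ms: float = 10.0,
) -> ApFeatures:
    """Extract waveform features of the AP peaking at ``peak_index``.

    Threshold is the voltage at the peak of the second derivative of V
    during the rise (from the preceding dV/dt-threshold crossing to the
    peak); amplitude is peak − threshold; FWHM is the width at the voltage
    midway between threshold and peak, with the crossings located by linear
    interpolation between samples.
    """
    v = trace.samples
    fs = trace.fs
    dv = _dvdt(v, fs)
    if not 0 < peak_index < v.size:
        raise ValueError("peak_index out of range")

    # rise onset: last sample before the peak where dV/dt is below threshold
    onset = peak_index
    i = peak_index - 1
    while i >= 0 and dv[i] >= dvdt_threshold_mv_per_ms:
        onset = i
        i -= 1
    if onset == peak_index:
        raise ValueError("no dV/dt-threshold crossing precedes the peak")

    # second derivative by first differences of dV/dt; d2[i] sits between
    # dv[i] and dv[i+1], i.e. at sample i+1 of V
    d2 = np.diff(dv) * fs / 1000.0
    lo = max(0, onset - 1)
    hi = max(lo + 1, peak_index - 1)
    thr_idx = lo + int(np.argmax(d2[lo:hi])) + 1
    threshold = float(v[thr_idx])
    peak = float(v[peak_index])
    if not peak > threshold:
        raise ValueError("malformed AP: peak does not exceed threshold")
    half = 0.5 * (threshold + peak)

    # rising half-height crossing (between threshold point and peak)
    j = thr_idx
    while j < peak_index and v[j + 1] < half:
        j += 1
    t_rise = (j + (half - v[j]) / (v[j + 1] - v[j])) / fs if v[j + 1] != v[j] else j / fs

    # falling half-height crossing within 10 ms after the peak
    limit = min(v.size - 1, peak_index + int(round(0.010 * fs)))
    k = peak_index
    while k < limit and v[k + 1] > half:
        k += 1
    if k == limit and v[min(k + 1, v.size - 1)] > half:
        raise ValueError("malformed AP: no falling half-height crossing within 10 ms")
    t_fall = (k + (half - v[k]) / (v[k + 1] - v[k])) / fs if v[k + 1] != v[k] else k / fs

    # excursion for dV/dt extrema: rise onset to return below threshold
    end = peak_index
    cap = min(v.size, peak_index + int(round(0.010 * fs)) + 1)
    while end < cap - 1 and v[end] > threshold:
        end += 1
    max_dvdt = float(dv[max(0, onset - 1) : end].max())
    min_dvdt = float(dv[peak_index:end].min()) if end > peak_index else float("nan")

    return ApFeatures(
        threshold_mv=threshold,
        amplitude_mv=peak - threshold,
        fwhm_ms=(t_fall - t_rise) * 1000.0,
        max_dvdt_mv_per_ms=max_dvdt,
        min_dvdt_mv_per_ms=min_dvdt,
        peak_mv=peak,
        peak_time_s=trace.t0 + peak_index / fs,
    )


def _window_indices(trace: Trace, t_start: float, t_end: float) -> tuple[int, int]:
    a = trace.index_at(t_start)
    b = trace.index_at(t_end)
    return a, max(a + 1, b)


def input_resistance(
    sweeps: SweepSet,
    steady_state_fraction: float = 0.25,
    dvdt_threshold_mv_per_ms: float = 10.0,
) -> float:
    """Input resistance in MΩ from the slope of the I–V plot.

    For each sweep, ΔV = (steady-state mean over the last
    ``steady_state_fraction`` of the step) − (baseline mean just before the
    step); the OLS slope of ΔV (mV) against I (pA) is the resistance in GΩ,
    returned in MΩ.  Sweeps containing an AP inside the measurement window
    are excluded with a warning; fewer than 3 usable sweeps is an error.
    """
    proto = sweeps.protocol
    step_len = proto.step_end_s - proto.step_start_s
    ss_start = proto.step_end_s - steady_state_fraction * step_len
    currents, dvs = [], []
    for sw in sweeps:
        tr = sw.trace
        aps = detect_aps(tr, dvdt_threshold_mv_per_ms)
        if aps.size:
            ap_t = tr.t0 + aps / tr.fs
            if np.any((ap_t >= proto.step_start_s) & (ap_t <= proto.step_end_s)):
                warnings.warn(
                    f"sweep at {sw.current_pa} pA contains APs; excluded from I-V fit"
                )
                continue
        a, b = _window_indices(tr, ss_start, proto.step_end_s)
        base_start = proto.step_start_s - proto.baseline_window_ms / 1000.0
        c, d = _window_indices(tr, max(tr.t0, base_start), proto.step_start_s)
        dvs.append(float(np.mean(tr.samples[a:b]) - np.mean(tr.samples[c:d])))
        currents.append(sw.current_pa)
    if len(currents) < 3:
        raise ValueError(f"need >= 3 usable subthreshold sweeps, got {len(currents)}")
    slope_gohm = float(np.polyfit(currents, dvs, 1)[0])  # mV/pA == GOhm
    return slope_gohm * 1000.0


def fi_curve(
    sweeps: SweepSet,
    dvdt_threshold_mv_per_ms: float = 10.0,
    min_peak_mv: float = -10.0,
) -> tuple[dict[float, int], float]:
    """Spike count per injected current and the OLS F–I slope (spikes/pA)."""
    proto = sweeps.protocol
    counts: dict[float, int] = {}
    for sw in sweeps:
        tr = sw.trace
        aps = detect_aps(tr, dvdt_threshold_mv_per_ms, min_peak_mv)
        ap_t = tr.t0 + aps / tr.fs
        n = int(np.sum((ap_t >= proto.step_start_s) & (ap_t <= proto.step_end_s)))
        counts[sw.current_pa] = n
    currents = np.array(sorted(counts))
    ns = np.array([counts[c] for c in currents], dtype=float)
    slope = float(np.polyfit(currents, ns, 1)[0]) if currents.size >= 2 else 0.0
    return counts, slope


def rheobase(
    sweeps: SweepSet,
    dvdt_threshold_mv_per_ms: float = 10.0,
    min_peak_mv: float = -10.0,
) -> Optional[float]:
    """Smallest injected current whose sweep fires at least one AP.

    Returns None (with a warning) when no sweep spikes.
    """
    counts, _ = fi_curve(sweeps, dvdt_threshold_mv_per_ms, min_peak_mv)
    spiking = [c for c in sorted(counts) if counts[c] >= 1]
    if not spiking:
        warnings.warn("no sweep fired an AP; rheobase undefined")
        return None
    return float(spiking[0])


def mahp_amplitude(
    trace: Trace,
    last_spike_time_s: float,
    baseline_window_ms: float = 100.0,
    post_window_ms: float = 500.0,
) -> float:
    """Medium-AHP amplitude after a spike train, in mV.

    Voltage difference between the mean over the first ``baseline_window_ms``
    of the sweep and the minimum within ``post_window_ms`` after the end of
    spikes.  Positive values mean hyperpolarization below baseline.
    """
    fs = trace.fs
    nb = int(round(baseline_window_ms / 1000.0 * fs))
    if nb < 1 or nb > len(trace):
        raise ValueError("baseline window does not fit the trace")
    end_t = last_spike_time_s + post_window_ms / 1000.0
    if end_t > trace.t0 + trace.duration_s + 0.5 / fs:
        raise ValueError("post-spike window extends past the end of the trace")
    baseline = float(np.mean(trace.samples[:nb]))
    a = trace.index_at(last_spike_time_s) + 1
    b = trace.index_at(end_t) + 1
    vmin = float(np.min(trace.samples[a:b]))
    return baseline - vmin


def tonic_current_shift(
    trace: Trace,
    drug_time_s: float,
    pre_window_s: float,
    post_window_s: float,
    gap_s: float = 1.0,
) -> float:
    """Baseline holding-current shift after drug application, in pA.

    shift = mean(pre-window) − mean(post-window), with ``gap_s`` on each side
    of the application excluded to avoid the transition transient.  Sign
    follows the direction of the displacement (a more negative holding
    current after the drug yields a positive shift).
    """
    t_end = trace.t0 + trace.duration_s
    pre_lo, pre_hi = drug_time_s - gap_s - pre_window_s, drug_time_s - gap_s
    post_lo, post_hi = drug_time_s + gap_s, drug_time_s + gap_s + post_window_s
    if pre_lo < trace.t0 or post_hi > t_end:
        raise ValueError("analysis windows fall outside the trace")
    a, b = _window_indices(trace, pre_lo, pre_hi)
    c, d = _window_indices(trace, post_lo, post_hi)
    return float(np.mean(trace.samples[a:b]) - np.mean(trace.samples[c:d]))


# ---------------------------------------------------------------------------
# Sweep-set I/O: HDF5 groups /sweeps/NNN with attributes current_pa plus the
# per-trace attributes, and a /protocol group carrying the step timing.


def write_sweeps(path: str | Path, sweeps: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("sweeps")
        for i, sw in enumerate(sweeps):
            ds = g.create_dataset(f"{i:03d}", data=sw.trace.samples, dtype="float64")
            ds.attrs["fs_hz"] = float(sw.trace.fs)
            ds.attrs["unit"] = sw.trace.unit.value
            ds.attrs["t0_s"] = float(sw.trace.t0)
            ds.attrs["current_pa"] = float(sw.current_pa)
        p = f.create_group("protocol")
        p.attrs["step_start_s"] = sweeps.protocol.step_start_s
        p.attrs["step_end_s"] = sweeps.protocol.step_end_s
        p.attrs["baseline_window_ms"] = sweeps.protocol.baseline_window_ms
        p.attrs["currents_pa"] = list(sweeps.protocol.currents_pa)


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        p = f["protocol"]
        proto = StepProtocol(
            step_start_s=float(p.attrs["step_start_s"]),
            step_end_s=float(p.attrs["step_end_s"]),
            currents_pa=tuple(float(v) for v in p.attrs["currents_pa"]),
            baseline_window_ms=float(p.attrs["baseline_window_ms"]),
        )
        sweeps = []
        for name in sorted(f["sweeps"]):
            ds = f["sweeps"][name]
            tr = Trace(
                samples=ds[()],
                fs=float(ds.attrs["fs_hz"]),
                unit=Unit(ds.attrs.get("unit", "mV")),
                t0=float(ds.attrs.get("t0_s", 0.0)),
            )
            sweeps.append(Sweep(trace=tr, current_pa=float(ds.attrs["current_pa"])))
    return SweepSet(sweeps=tuple(sweeps), protocol=proto)
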
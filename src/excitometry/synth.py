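"""Synthetic-data generators with ground truth.

Every stage of the pipeline can be exercised without animal recordings:

* :func:`simulate_adex` — an adaptive exponential integrate-and-fire
  (AdEx) neuron driven by a step protocol.  The model has closed-form
  passive properties (input resistance 1/g_leak at rest with a = 0, resting
  potential E_leak, rheobase g_leak·(V_T − E_leak − Δ_T)) and a mechanistic
  medium AHP through the adaptation current w, so parameter-recovery tests
  have analytic truth.
* :func:`synth_extracellular` — stationary Gaussian noise plus biphasic
  spike templates at known times (Poisson background and burst clusters)
  plus Hann-windowed sinusoidal LFP transients whose true duration is the
  window support.
* :func:`synth_proteome` — log-normal TMT-style abundance tables (three
  replicates per group) with planted fold changes.
* :func:`synth_seizure_cohort` — staged seizure latencies as ordered
  exponential arrivals with a group rate shift.

All generators are pure functions of their spec and seed.  Template and
transient peak amplitudes are expressed in multiples of the *raw* noise
standard deviation of the generated trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import SeizureRecord
from .patch import StepProtocol, Sweep, SweepSet
from .trace import Trace, Unit

__all__ = [
    "AdexParams",
    "ExtracellularScene",
    "SyntheticProteomeSpec",
    "simulate_adex",
    "synth_extracellular",
    "synth_proteome",
    "synth_seizure_cohort",
]


@dataclass(frozen=True)
class AdexParams:
    """Adaptive exponential integrate-and-fire parameters.

    Defaults describe a regular-spiking cortical neuron with input
    resistance 100 MΩ (g_leak = 10 nS), rest at −70 mV, and purely
    spike-triggered adaptation (a = 0, b = 60 pA) so the subthreshold I–V
    slope equals 1/g_leak exactly and the post-train AHP grows with b.
    """

    capacitance_pf: float = 150.0
    g_leak_ns: float = 10.0
    e_leak_mv: float = -70.0
    delta_t_mv: float = 2.0
    v_threshold_mv: float = -50.0
    v_reset_mv: float = -55.0
    v_peak_mv: float = 20.0
    tau_w_ms: float = 150.0
    a_ns: float = 0.0
    b_pa: float = 60.0
    noise_sd_pa: float = 0.0

    def __post_init__(self) -> None:
        if min(self.capacitance_pf, self.g_leak_ns, self.tau_w_ms) <= 0:
            raise ValueError("capacitance, g_leak and tau_w must be positive")
        if not self.v_peak_mv > self.v_threshold_mv > self.v_reset_mv:
            raise ValueError("need v_peak > v_threshold > v_reset")

    @property
    def input_resistance_mohm(self) -> float:
        """Analytic subthreshold input resistance, MΩ (1/(g_leak + a))."""
        return 1000.0 / (self.g_leak_ns + self.a_ns)

    @property
    def rheobase_pa(self) -> float:
        """Analytic rheobase of the exponential spike mechanism (a = 0)."""
        return self.g_leak_ns * (self.v_threshold_mv - self.e_leak_mv - self.delta_t_mv)


def simulate_adex(
    params: AdexParams,
    protocol: StepProtocol,
    fs: float = 20_000.0,
    seed: int = 0,
    sweep_duration_s: Optional[float] = None,
) -> tuple[SweepSet, dict]:
    """Simulate one sweep per protocol current; returns the sweep set and truth.

    Forward-Euler integration at dt = 1/fs of

        C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) + I + ξ − w
        τ_w dw/dt = a (V − E_L) − w

    with spike-and-reset at V ≥ v_peak (V ← v_reset, w ← w + b).  Truth holds
    per-sweep spike times, the analytic input resistance, resting potential
    and rheobase.  Deterministic given the seed.
    """
    dur = sweep_duration_s if sweep_duration_s is not None else protocol.step_end_s + 0.6
    n = int(round(dur * fs))
    dt = 1000.0 / fs  # ms
    C, gL, EL = params.capacitance_pf, params.g_leak_ns, params.e_leak_mv
    dT, VT = params.delta_t_mv, params.v_threshold_mv
    i_on = int(round(protocol.step_start_s * fs))
    i_off = int(round(protocol.step_end_s * fs))
    rng = np.random.default_rng(seed)

    sweeps: list[Sweep] = []
    spike_times: dict[float, np.ndarray] = {}
    for current in protocol.currents_pa:
        v = np.empty(n)
        V, w = EL, 0.0
        spikes: list[float] = []
        noise = rng.normal(0.0, params.noise_sd_pa, n) if params.noise_sd_pa > 0 else None
        for k in range(n):
            I = current if i_on <= k < i_off else 0.0
            if noise is not None:
                I += noise[k]
            exp_arg = min((V - VT) / dT, 30.0)
            dV = (-gL * (V - EL) + gL * dT * np.exp(exp_arg) + I - w) / C * dt
            dw = (params.a_ns * (V - EL) - w) / params.tau_w_ms * dt
            V += dV
            w += dw
            if not np.isfinite(V):
                raise FloatingPointError(
                    f"AdEx integration diverged at t={k / fs:.4f}s, I={current} pA"
                )
            if V >= params.v_peak_mv:
                spikes.append(k / fs)
                v[k] = params.v_peak_mv
                V = params.v_reset_mv
                w += params.b_pa
            else:
                v[k] = V
        tr = Trace(samples=v, fs=fs, unit=Unit.mV)
        sweeps.append(Sweep(trace=tr, current_pa=current))
        spike_times[current] = np.asarray(spikes)

    truth = {
        "spike_times": spike_times,
        "input_resistance_mohm": params.input_resistance_mohm,
        "rest_mv": params.e_leak_mv,
        "rheobase_pa": params.rheobase_pa,
    }
    return SweepSet(sweeps=tuple(sweeps), protocol=protocol), truth


@dataclass(frozen=True)
class ExtracellularScene:
    """Recipe for a synthetic extracellular trace.

    Spike templates are biphasic — one Hann-windowed sine cycle of width
    ``template_width_ms`` whose repolarization lobe is scaled to
    ``template_lobe_ratio`` of the dominant lobe, as in smoothed
    extracellular waveforms; the planted time is the dominant-lobe peak.
    ``template_peak_over_sigma`` and each LFP transient's peak are multiples
    of ``noise_sd``.  ``background_spike_times_s``, when given, replaces the
    Poisson background draw with explicit times.
    """

    duration_s: float = 10.0
    fs: float = 20_000.0
    noise_sd: float = 1.0
    template_width_ms: float = 6.0
    template_peak_over_sigma: float = 10.0
    template_lobe_ratio: float = 0.1
    background_rate_hz: float = 2.0
    burst_rate_hz: float = 0.0
    spikes_per_burst: int = 4
    intra_burst_isi_ms: float = 8.0  # < 10 ms so planted clusters meet the
    # burst criterion, > template lobe width so planted spikes stay separable
    lfp_events: tuple[tuple[float, float, float, float], ...] = ()  # (t, peak/σ, dur_ms, freq)
    seed: int = 0
    background_spike_times_s: Optional[tuple[float, ...]] = None
    n_bursts: Optional[int] = None  # exact burst count instead of a Poisson draw

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0 or self.burst_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if not self.intra_burst_isi_ms < 10.0:
            raise ValueError("intra-burst ISI must stay below the 10 ms burst criterion")


def _biphasic_template(width_ms: float, fs: float, lobe_ratio: float = 0.1) -> tuple[np.ndarray, int]:
    """Biphasic spike template: a Hann-windowed sine cycle whose negative
    (repolarization) lobe is scaled to ``lobe_ratio`` of the dominant lobe.
    Unit positive peak; returns (kernel, index of the peak within it)."""
    m = int(round(width_ms / 1000.0 * fs))
    if m < 4:
        raise ValueError("template too short for the sampling rate")
    t = np.arange(m)
    w = np.hanning(m) * np.sin(2 * np.pi * t / m)
    w[w < 0] *= lobe_ratio
    peak = int(np.argmax(w))
    return w / w[peak], peak


def synth_extracellular(scene: ExtracellularScene) -> tuple[Trace, dict]:
    """Generate a noise + spikes + LFP trace and its ground-truth tables.

    Truth: ``spike_times_s`` (all planted spikes, sorted), ``bursts``
    (start, end, n_spikes of each planted cluster) and ``lfp`` (time,
    duration, peak) tables.
    """
    n = int(round(scene.duration_s * scene.fs))
    rng = np.random.default_rng(scene.seed)
    x = rng.normal(0.0, scene.noise_sd, n)

    kernel, kpeak = _biphasic_template(
        scene.template_width_ms, scene.fs, scene.template_lobe_ratio
    )
    if kernel.size > n:
        raise ValueError("spike template wider than the trace")
    amp = scene.template_peak_over_sigma * scene.noise_sd

    spike_times: list[float] = []

    def plant(t_s: float) -> bool:
        i0 = int(round(t_s * scene.fs)) - kpeak
        if i0 < 0 or i0 + kernel.size > n:
            return False
        x[i0 : i0 + kernel.size] += amp * kernel
        spike_times.append(i0 / scene.fs + kpeak / scene.fs)
        return True

    margin = scene.template_width_ms / 1000.0
    if scene.background_spike_times_s is not None:
        for t in scene.background_spike_times_s:
            plant(t)
    elif scene.background_rate_hz > 0:
        n_bg = rng.poisson(scene.background_rate_hz * scene.duration_s)
        for t in np.sort(rng.uniform(margin, scene.duration_s - margin, n_bg)):
            plant(t)

    burst_rows: list[tuple[float, float, int]] = []
    if scene.burst_rate_hz > 0 or scene.n_bursts:
        n_b = (
            scene.n_bursts
            if scene.n_bursts is not None
            else rng.poisson(scene.burst_rate_hz * scene.duration_s)
        )
        isi = scene.intra_burst_isi_ms / 1000.0
        span = (scene.spikes_per_burst - 1) * isi
        for t0 in np.sort(rng.uniform(margin, scene.duration_s - margin - span, n_b)):
            planted = [t0 + k * isi for k in range(scene.spikes_per_burst)]
            if all(plant(t) for t in planted):
                burst_rows.append((planted[0], planted[-1], len(planted)))

    lfp_rows: list[tuple[float, float, float]] = []
    for t_s, peak_over_sigma, dur_ms, freq_hz in scene.lfp_events:
        m = int(round(dur_ms / 1000.0 * scene.fs))
        i0 = int(round(t_s * scene.fs)) - m // 2
        if i0 < 0 or i0 + m > n:
            raise ValueError(f"LFP event at {t_s}s does not fit the trace")
        tt = np.arange(m) / scene.fs
        x[i0 : i0 + m] += (
            peak_over_sigma * scene.noise_sd * np.hanning(m) * np.sin(2 * np.pi * freq_hz * tt)
        )
        lfp_rows.append((t_s, dur_ms, peak_over_sigma * scene.noise_sd))

    trace = Trace(samples=x, fs=scene.fs, unit=Unit.uV, channel_id="synthetic")
    truth = {
        "spike_times_s": np.sort(np.asarray(spike_times)),
        "bursts": pd.DataFrame(burst_rows, columns=["start_s", "end_s", "n_spikes"]),
        "lfp": pd.DataFrame(lfp_rows, columns=["time_s", "duration_ms", "peak"]),
    }
    return trace, truth


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Log-normal abundance table with planted fold changes.

    ``cv`` is the replicate coefficient of variation; planted rows are the
    first ``n_true_deps`` ids, scaled by ``true_fc`` in the cKO group.
    """

    n_rows: int = 1000
    n_reps_per_group: int = 3
    cv: float = 0.10
    n_true_deps: int = 0
    true_fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_deps > self.n_rows:
            raise ValueError("n_true_deps cannot exceed n_rows")
        if not self.cv > 0:
            raise ValueError("cv must be positive")


def synth_proteome(spec: SyntheticProteomeSpec) -> tuple[pd.DataFrame, list[str]]:
    """Generate a WT/cKO abundance table plus the list of true-DEP ids."""
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=spec.n_rows)
    sigma = np.sqrt(np.log1p(spec.cv**2))  # log-normal sd giving the requested CV
    k = spec.n_reps_per_group
    wt = base[:, None] * rng.lognormal(0.0, sigma, (spec.n_rows, k))
    ko = base[:, None] * rng.lognormal(0.0, sigma, (spec.n_rows, k))
    ko[: spec.n_true_deps] *= spec.true_fc
    ids = [f"P{i:05d}" for i in range(spec.n_rows)]
    table = pd.DataFrame(
        np.hstack([wt, ko]),
        index=pd.Index(ids, name="id"),
        columns=[f"WT_{j + 1}" for j in range(k)] + [f"cKO_{j + 1}" for j in range(k)],
    )
    return table, ids[: spec.n_true_deps]


def synth_seizure_cohort(
    n_per_group: int,
    rate_shift: float = 1.0,
    seed: int = 0,
    base_stage_rates_per_s: tuple[float, float, float] = (1 / 120.0, 1 / 180.0, 1 / 300.0),
    observation_s: float = 1800.0,
    stage2_event_mean: float = 4.0,
    stage2_event_duration_mean_s: float = 3.0,
) -> tuple[list[SeizureRecord], dict]:
    """Two synthetic cohorts of staged-seizure records.

    Stage latencies are ordered exponential arrivals (cumulative sums of
    exponential stage-to-stage gaps); the "shifted" group's hazard rates are
    multiplied by ``rate_shift`` (> 1 means earlier stages, higher scores).
    Stages arriving after the observation period are censored (not reached).
    """
    if rate_shift <= 0 or min(base_stage_rates_per_s) <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    records: list[SeizureRecord] = []
    for group, mult in (("control", 1.0), ("shifted", rate_shift)):
        rates = [r * mult for r in base_stage_rates_per_s]
        for i in range(n_per_group):
            gaps = [rng.exponential(1.0 / r) for r in rates]
            arrivals = np.cumsum(gaps)
            lat = {s + 1: float(t) for s, t in enumerate(arrivals) if t <= observation_s}
            events: tuple[tuple[float, float], ...] = ()
            if 2 in lat:
                n_ev = 1 + rng.poisson(stage2_event_mean * mult - 1 if stage2_event_mean * mult > 1 else 0)
                onsets = np.sort(rng.uniform(lat[2], observation_s, n_ev))
                durs = rng.exponential(stage2_event_duration_mean_s, n_ev)
                events = tuple((float(o), float(d)) for o, d in zip(onsets, durs))
            records.append(
                SeizureRecord(
                    latency_s=lat,
                    stage2_events=events,
                    observation_s=observation_s,
                    animal_id=f"{group}_{i:02d}",
                    group=group,
                )
            )
    truth = {"rate_shift": rate_shift, "base_stage_rates_per_s": base_stage_rates_per_s}
    return records, truth
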
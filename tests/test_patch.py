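"""Current-clamp stage: passive properties, AP features, F-I, mAHP."""

import warnings

import numpy as np
import pytest

from excitometry import patch, synth
from excitometry.patch import Sweep, SweepSet, StepProtocol
from excitometry.trace import Trace, Unit


def mv_trace(samples, fs=20_000.0):
    return Trace(samples=np.asarray(samples, dtype=float), fs=fs, unit=Unit.mV)


def piecewise_ap(
    fs=100_000.0,
    baseline=-60.0,
    slow_slope=0.5,
    kink_v=-45.0,
    fast_slope=100.0,
    peak=40.0,
):
    """Piecewise-linear AP: slow rise, kink to fast rise, symmetric fall.

    The kink is the unique curvature maximum, so the threshold estimate has
    a closed form.
    """
    dt_ms = 1000.0 / fs
    seg1 = np.arange(baseline, kink_v, slow_slope * dt_ms)
    seg2 = np.arange(kink_v, peak, fast_slope * dt_ms)
    seg3 = np.arange(peak, baseline, -fast_slope * dt_ms)
    v = np.concatenate([np.full(200, baseline), seg1, seg2, seg3, np.full(3000, baseline)])
    return mv_trace(v, fs)


def rc_sweepset(r_mohm=100.0, currents=(-150, -125, -100, -75, -50), noise_sd=0.0, seed=0):
    """Noiseless (or noisy) instantaneous-RC sweeps: dV = R * I during the step."""
    fs = 10_000.0
    proto = StepProtocol(step_start_s=0.2, step_end_s=0.7, currents_pa=tuple(float(c) for c in currents))
    rng = np.random.default_rng(seed)
    sweeps = []
    n = int(0.9 * fs)
    on, off = int(0.2 * fs), int(0.7 * fs)
    for c in proto.currents_pa:
        v = np.full(n, -70.0)
        v[on:off] += r_mohm / 1000.0 * c  # MOhm * pA = mV after /1000
        if noise_sd:
            v = v + rng.normal(0, noise_sd, n)
        sweeps.append(Sweep(trace=mv_trace(v, fs), current_pa=c))
    return SweepSet(sweeps=tuple(sweeps), protocol=proto)


class TestRestingMembranePotential:
    def test_constant(self):
        assert patch.resting_membrane_potential(mv_trace(np.full(10_000, -70.0))) == -70.0

    def test_noisy_within_standard_error(self, rng):
        n = 2000  # 100 ms at 20 kHz
        v = -70.0 + rng.normal(0, 0.5, 20_000)
        est = patch.resting_membrane_potential(mv_trace(v))
        se = 0.5 / np.sqrt(n)
        assert abs(est - (-70.0)) < 3 * se * 10  # correlated-free iid bound, generous

    def test_simulated_rest_at_leak_reversal(self):
        proto = StepProtocol(step_start_s=0.5, step_end_s=0.6, currents_pa=(0.0,))
        ss, _ = synth.simulate_adex(synth.AdexParams(), proto, fs=20_000.0)
        rmp = patch.resting_membrane_potential(ss.sweeps[0].trace)
        assert rmp == pytest.approx(-70.0, abs=0.1)

    def test_window_longer_than_trace(self):
        with pytest.raises(ValueError):
            patch.resting_membrane_potential(mv_trace(np.zeros(10), fs=1000.0), 100.0)


class TestInputResistance:
    def test_linear_sweeps_exact(self):
        assert patch.input_resistance(rc_sweepset(100.0)) == pytest.approx(100.0, rel=1e-12)

    def test_zero_response_zero_resistance(self):
        assert patch.input_resistance(rc_sweepset(0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_offset_invariance(self):
        ss = rc_sweepset(80.0)
        shifted = SweepSet(
            sweeps=tuple(
                Sweep(trace=s.trace.with_samples(s.trace.samples + 13.5), current_pa=s.current_pa)
                for s in ss
            ),
            protocol=ss.protocol,
        )
        assert patch.input_resistance(shifted) == pytest.approx(patch.input_resistance(ss))

    def test_noisy_recovery_within_5pct(self):
        ss = rc_sweepset(100.0, currents=tuple(range(-150, 10, 10)), noise_sd=0.5, seed=4)
        assert patch.input_resistance(ss) == pytest.approx(100.0, rel=0.05)

    def test_simulated_neuron_10ns_leak(self):
        proto = StepProtocol(step_start_s=0.2, step_end_s=0.7, currents_pa=tuple(range(-150, -40, 10)))
        ss, truth = synth.simulate_adex(synth.AdexParams(g_leak_ns=10.0), proto)
        assert patch.input_resistance(ss) == pytest.approx(truth["input_resistance_mohm"], rel=0.05)

    def test_too_few_sweeps_rejected(self):
        ss = rc_sweepset(100.0, currents=(-100, -50))
        with pytest.raises(ValueError):
            patch.input_resistance(ss)


class TestDetectAps:
    def test_subthreshold_rc_response_has_none(self):
        ss = rc_sweepset(100.0)
        assert patch.detect_aps(ss.sweeps[0].trace).size == 0

    def test_inserted_stylized_aps_found_at_peaks(self, rng):
        # oracle: the known insertion times
        fs = 20_000.0
        v = np.full(int(2 * fs), -65.0) + rng.normal(0, 0.2, int(2 * fs))
        width = int(0.002 * fs)
        ap = 90.0 * np.hanning(2 * width)  # 2 ms rise to +25 mV, 2 ms fall
        inserted = []
        for t in np.linspace(0.2, 1.8, 7):
            i0 = int(t * fs) - width
            v[i0 : i0 + 2 * width] += ap
            inserted.append(i0 + int(np.argmax(ap)))
        peaks = patch.detect_aps(mv_trace(v, fs))
        assert peaks.size == 7
        np.testing.assert_allclose(peaks, inserted, atol=3)

    def test_matches_simulator_spike_count(self):
        proto = StepProtocol(step_start_s=0.2, step_end_s=1.2, currents_pa=(300.0,))
        ss, truth = synth.simulate_adex(synth.AdexParams(), proto)
        peaks = patch.detect_aps(ss.sweeps[0].trace)
        assert peaks.size == len(truth["spike_times"][300.0])


class TestApWaveformFeatures:
    def test_piecewise_linear_closed_form(self):
        tr = piecewise_ap()
        peak = int(patch.detect_aps(tr)[0])
        f = patch.ap_waveform_features(tr, peak)
        assert f.threshold_mv == pytest.approx(-45.0, abs=0.01)
        assert f.amplitude_mv == pytest.approx(85.0, abs=0.02)
        assert f.max_dvdt_mv_per_ms == pytest.approx(100.0, rel=1e-6)
        assert f.min_dvdt_mv_per_ms == pytest.approx(-100.0, rel=1e-6)
        # half-height -2.5 mV; width 2*(40-(-2.5))/100 = 0.85 ms
        assert f.fwhm_ms == pytest.approx(0.85, abs=0.005)

    def test_amplitude_identity(self):
        tr = piecewise_ap()
        f = patch.ap_waveform_features(tr, int(patch.detect_aps(tr)[0]))
        assert f.amplitude_mv == pytest.approx(f.peak_mv - f.threshold_mv)

    @pytest.mark.parametrize("seed", range(5))
    def test_fwhm_of_symmetric_triangle(self, seed):
        # closed form: a symmetric triangular spike's width above half-height
        # is half its base width
        rng = np.random.default_rng(seed)
        fs = 100_000.0
        baseline = -60.0
        kink = rng.uniform(-50, -40)
        peak = rng.uniform(20, 50)
        slope = rng.uniform(60, 150)
        tr = piecewise_ap(fs=fs, kink_v=kink, fast_slope=slope, peak=peak)
        f = patch.ap_waveform_features(tr, int(patch.detect_aps(tr)[0]))
        base_width_ms = 2 * (peak - kink) / slope
        assert f.fwhm_ms == pytest.approx(base_width_ms / 2, abs=0.01)

    def test_adex_threshold_brackets_rise(self):
        # a truncated-exponential upswing has no interior curvature maximum,
        # so the estimate lands between the rise onset and the peak
        proto = StepProtocol(step_start_s=0.1, step_end_s=0.6, currents_pa=(300.0,))
        ss, _ = synth.simulate_adex(synth.AdexParams(), proto, fs=100_000.0)
        tr = ss.sweeps[0].trace
        f = patch.ap_waveform_features(tr, int(patch.detect_aps(tr)[0]))
        assert -50.0 < f.threshold_mv < f.peak_mv

    def test_malformed_ap_rejected(self):
        # rises but never falls below half-height within 10 ms
        fs = 20_000.0
        v = np.concatenate([np.full(1000, -60.0), np.linspace(-60, 40, 20), np.full(1000, 40.0)])
        with pytest.raises(ValueError, match="malformed"):
            patch.ap_waveform_features(mv_trace(v, fs), 1019)


class TestFiCurveAndRheobase:
    @staticmethod
    def counts_sweepset(counts_at):
        """Sweeps with stylized APs giving exact per-current counts."""
        fs = 20_000.0
        proto = StepProtocol(step_start_s=0.2, step_end_s=1.0, currents_pa=tuple(sorted(counts_at)))
        width = int(0.001 * fs)
        sweeps = []
        for c, n_aps in sorted(counts_at.items()):
            v = np.full(int(1.2 * fs), -65.0)
            v[:200] += np.linspace(0, 0.001, 200)  # break exact constancy
            for k in range(n_aps):
                i0 = int((0.3 + 0.05 * k) * fs)
                v[i0 : i0 + 2 * width] += 90.0 * np.hanning(2 * width)
            sweeps.append(Sweep(trace=mv_trace(v, fs), current_pa=float(c)))
        return SweepSet(sweeps=tuple(sweeps), protocol=proto)

    def test_collinear_counts_exact_slope(self):
        ss = self.counts_sweepset({0: 0, 25: 2, 50: 4, 75: 6})
        counts, slope = patch.fi_curve(ss)
        assert counts == {0.0: 0, 25.0: 2, 50.0: 4, 75.0: 6}
        assert slope == pytest.approx(0.08, rel=1e-12)

    def test_all_zero_counts(self):
        ss = self.counts_sweepset({0: 0, 25: 0, 50: 0})
        counts, slope = patch.fi_curve(ss)
        assert slope == 0.0 and set(counts.values()) == {0}

    def test_simulated_counts_nondecreasing(self):
        proto = StepProtocol(step_start_s=0.2, step_end_s=1.2, currents_pa=tuple(range(0, 501, 50)))
        ss, _ = synth.simulate_adex(synth.AdexParams(), proto)
        counts, _ = patch.fi_curve(ss)
        ns = [counts[c] for c in sorted(counts)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_rheobase_first_spiking_sweep(self):
        ss = self.counts_sweepset({40: 0, 50: 0, 60: 1, 70: 3})
        assert patch.rheobase(ss) == 60.0

    def test_rheobase_absent_when_silent(self):
        ss = self.counts_sweepset({0: 0, 25: 0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert patch.rheobase(ss) is None

    def test_rheobase_within_one_increment_of_bisection_oracle(self):
        params = synth.AdexParams()
        proto = StepProtocol(step_start_s=0.2, step_end_s=1.2, currents_pa=tuple(range(0, 301, 10)))
        ss, _ = synth.simulate_adex(params, proto)
        measured = patch.rheobase(ss)

        def spikes_at(i_pa):
            p = StepProtocol(step_start_s=0.2, step_end_s=1.2, currents_pa=(i_pa,))
            _, truth = synth.simulate_adex(params, p)
            return len(truth["spike_times"][i_pa]) > 0

        lo, hi = 0.0, 300.0
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if spikes_at(mid):
                hi = mid
            else:
                lo = mid
        assert abs(measured - hi) <= 10.0


class TestMahpAndTonicShift:
    def test_worked_examples(self):
        fs = 1000.0
        v = np.full(2000, -70.0)
        v[1000:1100] = -75.0  # post-train dip
        tr = mv_trace(v, fs)
        assert patch.mahp_amplitude(tr, last_spike_time_s=0.9) == pytest.approx(5.0)
        flat = mv_trace(np.full(2000, -70.0), fs)
        assert patch.mahp_amplitude(flat, 0.9) == pytest.approx(0.0)

    def test_window_past_trace_end_rejected(self):
        tr = mv_trace(np.full(1000, -70.0), 1000.0)
        with pytest.raises(ValueError):
            patch.mahp_amplitude(tr, last_spike_time_s=0.9)

    def test_mahp_grows_with_adaptation_increment(self):
        # a short strong step with slow w-decay isolates the per-spike
        # adaptation increment: the post-train dip must deepen with b
        # (during *sustained* firing adaptation self-limits, so a long step
        # would not discriminate)
        proto = StepProtocol(step_start_s=0.2, step_end_s=0.35, currents_pa=(600.0,))
        amps = []
        for b in (20.0, 60.0, 120.0):
            ss, truth = synth.simulate_adex(
                synth.AdexParams(b_pa=b, tau_w_ms=500.0), proto,
                fs=20_000.0, sweep_duration_s=1.0,
            )
            last = truth["spike_times"][600.0][-1]
            amps.append(patch.mahp_amplitude(ss.sweeps[0].trace, last))
        assert amps[0] < amps[1] < amps[2]

    def test_tonic_shift_examples(self, rng):
        fs = 1000.0
        n = int(70 * fs)
        x = np.zeros(n)
        x[int(35 * fs) :] = -20.0
        tr = Trace(samples=x, fs=fs, unit=Unit.pA)
        shift = patch.tonic_current_shift(tr, 35.0, pre_window_s=30.0, post_window_s=30.0)
        assert shift == pytest.approx(20.0)
        flat = Trace(samples=np.zeros(n), fs=fs, unit=Unit.pA)
        assert patch.tonic_current_shift(flat, 35.0, 30.0, 30.0) == 0.0

    def test_tonic_shift_noisy_within_se(self, rng):
        fs = 1000.0
        n = int(70 * fs)
        x = rng.normal(0, 2.0, n)
        x[int(35 * fs) :] -= 15.0
        tr = Trace(samples=x, fs=fs, unit=Unit.pA)
        shift = patch.tonic_current_shift(tr, 35.0, 30.0, 30.0)
        se = 2.0 * np.sqrt(2.0 / (30 * fs))
        assert shift == pytest.approx(15.0, abs=3 * se)

    def test_windows_out_of_range(self):
        tr = Trace(samples=np.zeros(1000), fs=1000.0, unit=Unit.pA)
        with pytest.raises(ValueError):
            patch.tonic_current_shift(tr, 0.5, 10.0, 10.0)


class TestSweepIO:
    def test_round_trip(self, tmp_path):
        ss = rc_sweepset(100.0)
        p = tmp_path / "sweeps.h5"
        patch.write_sweeps(p, ss)
        back = patch.read_sweeps(p)
        assert back.protocol == ss.protocol
        assert len(back) == len(ss)
        for a, b in zip(back, ss):
            assert a.current_pa == b.current_pa
            np.testing.assert_array_equal(a.trace.samples, b.trace.samples)
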
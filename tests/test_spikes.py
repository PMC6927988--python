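"""Spike detection and AP/train measurements, validated against
analytic waveforms, brute-force re-implementations and simulator ground
truth."""

import numpy as np
import pytest

from spikephase import (
    CellRecording,
    NeuronParams,
    ProtocolSpec,
    ap_mahp,
    ap_shape,
    ap_threshold,
    detect_spikes,
    find_n_spike_sweep,
    find_rheobase,
    fi_curve,
    isi_accommodation,
    simulate_cell,
)
from spikephase.passive import FeatureUndefined
from spikephase.spikes import APEvent, analyze_sweep, dvdt, extract_cell_features

from conftest import make_sweep_from_arrays

FS = 50_000.0
DT = 1000.0 / FS


def _gauss_spike_trace(spike_times_ms, total_ms=700.0, baseline=-70.0,
                       height=110.0, sigma_ms=0.3):
    t = np.arange(0, total_ms, DT)
    v = np.full_like(t, baseline)
    for ts in spike_times_ms:
        v += height * np.exp(-0.5 * ((t - ts) / sigma_ms) ** 2)
    return t, v


def _ladder_recording(counts_by_amp, onset=100.0, offset=600.0):
    """Recording whose sweep at each amplitude contains a given number
    of synthetic spikes inside the step window."""
    sweeps = []
    for amp, n in counts_by_amp:
        times = onset + 50.0 + 30.0 * np.arange(n)
        _, v = _gauss_spike_trace(times)
        sweeps.append(make_sweep_from_arrays(
            v, sampling_rate=FS, step_amplitude=amp, step_onset=onset,
            step_offset=offset))
    return CellRecording(cell_id="synthetic", sweeps=sweeps)


class TestDetection:
    def test_subthreshold_sweep_empty(self):
        s = make_sweep_from_arrays(np.full(5000, -70.0))
        assert detect_spikes(s) == []

    def test_simulated_spikes_match_ground_truth(self, default_cell):
        """Detected peaks must sit within 1 ms of the simulator's true
        spike times on every ladder sweep."""
        rec, gt = default_cell
        for sweep, times in zip(rec.sweeps, gt.spike_times):
            events = detect_spikes(sweep)
            assert len(events) == len(times)
            for ev, t_true in zip(events, times):
                assert abs(ev.peak_time - t_true) < 1.0

    def test_merged_depolarizations_count_once(self):
        """Two humps that never repolarize below the criterion are one
        event (refractory guard)."""
        t = np.arange(0, 20, DT)
        v = (-70.0 + 110.0 * np.exp(-0.5 * ((t - 8) / 1.0) ** 2)
             + 100.0 * np.exp(-0.5 * ((t - 10) / 1.0) ** 2))
        assert v[int(8.0 / DT):int(10.0 / DT)].min() > 0.0
        s = make_sweep_from_arrays(v, sampling_rate=FS)
        assert len(detect_spikes(s)) == 1


class TestThreshold:
    def test_analytic_crossing_recovered(self, sigmoid_spike):
        """The 20 V/s crossing designed at -34.0 mV is recovered within
        0.2 mV."""
        sweep = sigmoid_spike.sweep()
        ev = detect_spikes(sweep)[0]
        thr = ap_threshold(sweep, ev)
        assert thr == pytest.approx(sigmoid_spike.threshold_voltage, abs=0.2)

    def test_resolution_robustness(self, sigmoid_spike):
        """Doubling the sampling rate moves the estimate by < 0.2 mV."""
        thrs = []
        for fs in (50_000.0, 100_000.0):
            sweep = sigmoid_spike.sweep(sampling_rate=fs)
            ev = detect_spikes(sweep)[0]
            thrs.append(ap_threshold(sweep, ev))
        assert abs(thrs[1] - thrs[0]) < 0.2

    def test_slow_ramp_rejected(self):
        """A 10 V/s ramp never reaches the criterion: not a spike."""
        t = np.arange(0, 20, DT)
        v = -70.0 + 10.0 * t  # 10 mV/ms throughout
        s = make_sweep_from_arrays(v, sampling_rate=FS)
        ev = APEvent(index=0, peak_index=v.size - 1,
                     peak_time=(v.size - 1) * DT, peak_voltage=v[-1])
        with pytest.raises(FeatureUndefined, match="not a spike"):
            ap_threshold(s, ev)


class TestShape:
    def test_triangle_geometry(self):
        """Isosceles triangle from -35 to +45 over a 2 ms base:
        amplitude 80 mV, half-width 1.0 ms."""
        t = np.arange(0, 20, DT)
        apex, rise = 10.0, 1.0
        v = np.full_like(t, -35.0)
        up = (t >= apex - rise) & (t <= apex)
        dn = (t > apex) & (t <= apex + rise)
        v[up] = -35.0 + 80.0 * (t[up] - (apex - rise)) / rise
        v[dn] = 45.0 - 80.0 * (t[dn] - apex) / rise
        s = make_sweep_from_arrays(v, sampling_rate=FS)
        peak = int(np.argmax(v))
        ev = APEvent(index=0, peak_index=peak, peak_time=peak * DT,
                     peak_voltage=v[peak],
                     threshold_index=int((apex - rise) / DT),
                     threshold_time=apex - rise, threshold_voltage=-35.0)
        ap_shape(s, ev)
        assert ev.peak_amplitude == pytest.approx(80.0, abs=0.01)
        assert ev.half_width == pytest.approx(1.0, abs=DT)
        assert ev.dvdt_max == pytest.approx(-ev.dvdt_min, rel=1e-6)

    def test_gaussian_fwhm(self):
        """With threshold at the baseline, half-width equals the
        Gaussian FWHM 2.355 sigma within one sample."""
        sigma = 0.4
        t, v = _gauss_spike_trace([10.0], total_ms=20.0, sigma_ms=sigma)
        s = make_sweep_from_arrays(v, sampling_rate=FS)
        peak = int(np.argmax(v))
        ev = APEvent(index=0, peak_index=peak, peak_time=peak * DT,
                     peak_voltage=v[peak], threshold_index=0,
                     threshold_time=0.0, threshold_voltage=-70.0)
        ap_shape(s, ev)
        assert ev.half_width == pytest.approx(2.3548 * sigma, abs=DT)

    def test_unrecovered_repolarization_flagged(self):
        t = np.arange(0, 20, DT)
        v = -70.0 + 110.0 / (1.0 + np.exp(-(t - 10.0) / 0.2))  # step up, stays up
        s = make_sweep_from_arrays(v, sampling_rate=FS)
        ev = detect_spikes(s)[0]
        ap_threshold(s, ev)
        ap_shape(s, ev)
        assert np.isnan(ev.half_width)
        assert "half_width" in ev.flags


class TestMahp:
    def _event(self, v, thr=-40.0):
        peak = int(np.argmax(v))
        return APEvent(index=0, peak_index=peak, peak_time=peak * DT,
                       peak_voltage=v[peak], threshold_index=peak - 10,
                       threshold_time=(peak - 10) * DT, threshold_voltage=thr)

    def test_monotone_decay_arithmetic(self):
        """Trough at threshold - 17 mV inside the window -> mAHP 17."""
        t = np.arange(0, 300, DT)
        v = np.full_like(t, -40.0)
        v[t < 50.0] = -40.0
        spike = np.exp(-0.5 * ((t - 50.0) / 0.3) ** 2) * 80.0
        after = t > 50.0
        v = v + spike
        v[after] += -17.0 * (1 - np.exp(-(t[after] - 50.0) / 10.0))
        s = make_sweep_from_arrays(v, sampling_rate=FS, step_onset=0.0,
                                   step_offset=300.0)
        ev = self._event(v)
        assert ap_mahp(s, ev) == pytest.approx(17.0, abs=0.05)

    def test_window_boundary_rule(self):
        """A deeper trough at 120 ms post-peak is outside the 100 ms
        window; the shallower minimum at 80 ms wins."""
        t = np.arange(0, 300, DT)
        v = np.full_like(t, -40.0) + 80.0 * np.exp(-0.5 * ((t - 50.0) / 0.3) ** 2)
        v -= 5.0 * np.exp(-0.5 * ((t - 130.0) / 5.0) ** 2)   # 80 ms post peak
        v -= 12.0 * np.exp(-0.5 * ((t - 170.0) / 5.0) ** 2)  # 120 ms post peak
        s = make_sweep_from_arrays(v, sampling_rate=FS, step_onset=0.0,
                                   step_offset=300.0)
        ev = self._event(v)
        assert ap_mahp(s, ev) == pytest.approx(5.0, abs=0.1)

    def test_gsk_monotonicity(self, short_protocol):
        """Doubling the SK conductance strictly deepens the mAHP."""
        mahps = []
        for gsk in (8.0, 16.0):
            rec, _ = simulate_cell(NeuronParams(gsk=gsk), short_protocol,
                                   seed=4)
            ap = extract_cell_features(rec).rheobase_ap
            mahps.append(ap.mahp)
        assert mahps[1] > mahps[0]


class TestRheobase:
    def test_rule_on_constructed_ladder(self):
        rec = _ladder_recording([(100.0, 0), (110.0, 1), (120.0, 3)])
        rheo, latency, sweep = find_rheobase(rec)
        assert rheo == 110.0
        assert sweep.step_amplitude == 110.0
        assert latency == pytest.approx(50.0, abs=1.0)

    def test_ladder_floor_flagged(self):
        rec = _ladder_recording([(50.0, 2), (100.0, 4)])
        fs = extract_cell_features(rec)
        assert fs.train.rheobase == 50.0
        assert "ladder-floor" in fs.train.flags.get("rheobase", "")

    def test_no_spikes_not_computable(self):
        rec = _ladder_recording([(100.0, 0), (200.0, 0)])
        with pytest.raises(FeatureUndefined):
            find_rheobase(rec)

    def test_within_one_increment_of_bisection_oracle(self, default_cell):
        """Brute-force bisection on the simulator itself brackets the
        true rheobase; the ladder estimate must sit within one 50 pA
        increment above it."""
        rec, gt = default_cell
        rheo, _, _ = find_rheobase(rec)

        def spikes_at(amp):
            proto = ProtocolSpec(step_amplitudes=(amp,))
            _, g = simulate_cell(gt.params, proto, seed=0)
            return len(g.spike_times[0]) > 0

        lo, hi = 0.0, rheo
        assert spikes_at(hi)
        while hi - lo > 2.0:
            mid = (lo + hi) / 2
            if spikes_at(mid):
                hi = mid
            else:
                lo = mid
        assert rheo - 50.0 <= hi <= rheo


class TestNSpikeSweep:
    def test_exact_count_preferred(self):
        rec = _ladder_recording([(100.0, 1), (150.0, 3), (200.0, 7),
                                 (250.0, 12)])
        sweep, cur, count, approx = find_n_spike_sweep(rec, 7)
        assert (cur, count, approx) == (200.0, 7, False)

    def test_nearest_below_fallback(self):
        rec = _ladder_recording([(100.0, 1), (150.0, 3), (200.0, 6),
                                 (250.0, 8)])
        sweep, cur, count, approx = find_n_spike_sweep(rec, 7)
        assert (cur, count, approx) == (200.0, 6, True)

    def test_tie_breaks_to_lower_current(self):
        rec = _ladder_recording([(200.0, 7), (250.0, 7)])
        _, cur, _, approx = find_n_spike_sweep(rec, 7)
        assert cur == 200.0 and not approx


class TestTrainMetrics:
    @pytest.mark.parametrize("isis,expected", [
        (np.full(6, 30.0), 0.0),
        ([20.0, 25, 30, 35, 38, 40.0], 0.5),
        ([50.0, 48, 46, 44, 42, 40.0], -0.25),
    ])
    def test_accommodation_arithmetic(self, isis, expected):
        times = np.concatenate([[100.0], 100.0 + np.cumsum(isis)])
        isi1, isi6, ratio = isi_accommodation(times)
        assert isi1 == pytest.approx(isis[0])
        assert isi6 == pytest.approx(isis[5])
        assert ratio == pytest.approx(expected)

    def test_too_few_spikes_undefined(self):
        with pytest.raises(FeatureUndefined, match="7"):
            isi_accommodation(np.arange(6) * 30.0)

    def test_fi_all_zero_for_subthreshold_ladder(self):
        rec = _ladder_recording([(50.0, 0), (100.0, 0)])
        assert fi_curve(rec) == [(50.0, 0.0), (100.0, 0.0)]

    def test_fi_matches_ground_truth_and_monotone(self, default_cell):
        rec, gt = default_cell
        fi = fi_curve(rec)
        truth = {
            s.step_amplitude: sum(
                1 for t in times
                if s.step_onset <= t < s.step_offset)
            for s, times in zip(rec.sweeps, gt.spike_times)
        }
        for amp, count in fi:
            assert count == truth[amp]
        counts = [c for _, c in fi]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestOracleEquivalence:
    def test_brute_force_agreement_on_simulated_sweep(self, default_cell):
        """Naive re-implementations of the definitions (forward scans on
        raw arrays, no interpolation or guards) agree with the
        production extractor within a sample / 0.5 mV."""
        rec, _ = default_cell
        _, _, sweep = find_rheobase(rec)
        events = analyze_sweep(sweep)
        d = dvdt(sweep.voltage, sweep.dt)
        v = sweep.voltage
        ev = events[0]
        # threshold: first supra-criterion sample before the peak
        idx = np.flatnonzero(d[:ev.peak_index] >= 20.0)
        naive_thr = v[idx[0]]
        assert abs(naive_thr - ev.threshold_voltage) < 0.5
        # half-width: sample count above the half level
        half = naive_thr + (v[ev.peak_index] - naive_thr) / 2
        seg = v[idx[0]:idx[0] + int(10.0 / sweep.dt)]
        naive_hw = np.sum(seg >= half) * sweep.dt
        assert abs(naive_hw - ev.half_width) <= 2 * sweep.dt + 0.05
        # mAHP: trough in the raw 100 ms window after the peak
        end = ev.peak_index + int(100.0 / sweep.dt)
        nxt = events[1].threshold_index if len(events) > 1 else end
        naive_mahp = naive_thr - v[ev.peak_index:min(end, nxt)].min()
        assert abs(naive_mahp - ev.mahp) < 0.5

    def test_shift_equivariance(self, default_cell):
        """Adding a constant to the trace shifts threshold and peak but
        leaves latency, half-width and mAHP unchanged."""
        rec, _ = default_cell
        _, _, sweep = find_rheobase(rec)
        ev0 = analyze_sweep(sweep)[0]
        shifted = make_sweep_from_arrays(
            sweep.voltage + 5.0, sampling_rate=sweep.sampling_rate,
            current=sweep.current, step_amplitude=sweep.step_amplitude,
            step_onset=sweep.step_onset, step_offset=sweep.step_offset)
        ev1 = analyze_sweep(shifted)[0]
        assert ev1.threshold_voltage == pytest.approx(
            ev0.threshold_voltage + 5.0, abs=1e-6)
        assert ev1.peak_voltage == pytest.approx(ev0.peak_voltage + 5.0)
        assert ev1.threshold_time == pytest.approx(ev0.threshold_time,
                                                   abs=1e-9)
        assert ev1.half_width == pytest.approx(ev0.half_width, abs=1e-9)
        assert ev1.mahp == pytest.approx(ev0.mahp, abs=1e-9)
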
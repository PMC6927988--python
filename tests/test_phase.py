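"""Phase plots and the AIS/SD decomposition, validated against the
analytic two-sigmoid construction and simulator monotonicity."""

import numpy as np
import pytest

from spikephase import (
    NeuronParams,
    ProtocolSpec,
    detect_spikes,
    find_breakpoint,
    first_ap_of_train,
    phase_plot,
    simulate_cell,
    slope_sd_ratio,
    two_sigmoid_spike,
)
from spikephase.passive import FeatureUndefined
from spikephase.spikes import analyze_sweep, ap_threshold, second_derivative

from conftest import make_sweep_from_arrays

FS = 50_000.0
DT = 1000.0 / FS


def _prepared_event(sweep):
    ev = detect_spikes(sweep)[0]
    ap_threshold(sweep, ev)
    return ev


class TestAnalyticOracle:
    def test_breakpoint_matches_analytic_argmin(self, sigmoid_spike):
        """The located trough must sit within 1 sample of the argmin of
        the exact analytic second derivative."""
        sweep = sigmoid_spike.sweep()
        ev = _prepared_event(sweep)
        bp = find_breakpoint(sweep, ev)
        assert abs(bp.time - sigmoid_spike.breakpoint_time) <= DT

    def test_ratio_matches_designed_value(self, sigmoid_spike):
        sweep = sigmoid_spike.sweep()
        ev = _prepared_event(sweep)
        dec = slope_sd_ratio(sweep, ev)
        assert dec.slope_sd_ratio == pytest.approx(sigmoid_spike.sd_ratio,
                                                   rel=0.01)
        assert dec.b == pytest.approx(sigmoid_spike.peak_slope, rel=0.01)

    def test_ais_peak_convention(self, sigmoid_spike):
        """Under the alternative convention the shoulder is the AIS
        component's own maximal slope: a = 400 - 100 = 300, ratio 0.75."""
        sweep = sigmoid_spike.sweep()
        ev = _prepared_event(sweep)
        dec = slope_sd_ratio(sweep, ev, convention="ais_peak")
        designed = 1.0 - (sigmoid_spike.ais_peak_slope
                          / sigmoid_spike.peak_slope)
        assert dec.slope_sd_ratio == pytest.approx(designed, rel=0.01)
        assert dec.convention == "ais_peak"

    def test_single_sigmoid_is_monophasic(self):
        """An upstroke with one kinetic component has no curvature
        trough: the decomposition is undefined."""
        w = two_sigmoid_spike(ais_peak_slope=400.0, sd_peak_slope=400.0,
                              separation=0.0)
        sweep = w.sweep()
        ev = _prepared_event(sweep)
        with pytest.raises(FeatureUndefined, match="monophasic|local minimum"):
            find_breakpoint(sweep, ev)


class TestPhasePlot:
    def test_triangle_is_two_valued_rectangle(self):
        t = np.arange(0, 20, DT)
        apex, rise = 10.0, 1.0
        v = np.full_like(t, -70.0)
        up = (t >= apex - rise) & (t <= apex)
        dn = (t > apex) & (t <= apex + rise)
        v[up] = -70.0 + 115.0 * (t[up] - (apex - rise)) / rise
        v[dn] = 45.0 - 115.0 * (t[dn] - apex) / rise
        sweep = make_sweep_from_arrays(v, sampling_rate=FS)
        ev = _prepared_event(sweep)
        vv, dd = phase_plot(sweep, ev)
        interior = dd[3:-3]
        rates = np.unique(np.round(interior, 3))
        # only the two ramp slopes (plus corner-interpolation samples)
        assert np.isclose(rates.max(), 115.0, atol=1.0)
        assert np.isclose(rates.min(), -115.0, atol=1.0)

    def test_simulated_ap_loop_has_positive_span(self, default_cell):
        rec, _ = default_cell
        sweep = rec.depolarizing_sweeps()[-1]
        ev = analyze_sweep(sweep)[0]
        vv, dd = phase_plot(sweep, ev)
        assert dd.max() > 100.0 and dd.min() < -20.0
        assert vv.max() > 0.0

    def test_constant_trace_flat_phase(self):
        sweep = make_sweep_from_arrays(np.full(1000, -65.0), sampling_rate=FS)
        d = np.gradient(sweep.voltage, sweep.dt)
        assert np.allclose(d, 0.0)


class TestSecondDerivativeOracle:
    def test_matches_double_central_difference(self, sigmoid_spike):
        """The production stencil and central differences applied twice
        agree to O(dt^2) in value, and place the rising-phase trough at
        the same sample."""
        sweep = sigmoid_spike.sweep()
        d2 = second_derivative(sweep.voltage, sweep.dt)
        oracle = np.gradient(np.gradient(sweep.voltage, sweep.dt), sweep.dt)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(d2[2:-2] - oracle[2:-2])) < 0.05 * scale
        assert abs(int(np.argmin(d2)) - int(np.argmin(oracle))) <= 1
        # at double sampling the stencil disagreement falls ~4x
        sweep2 = sigmoid_spike.sweep(sampling_rate=100_000.0)
        d2b = second_derivative(sweep2.voltage, sweep2.dt)
        oracle2 = np.gradient(np.gradient(sweep2.voltage, sweep2.dt),
                              sweep2.dt)
        err2 = np.max(np.abs(d2b[2:-2] - oracle2[2:-2]))
        assert err2 < 0.4 * np.max(np.abs(d2[2:-2] - oracle[2:-2]))


class TestInvariants:
    def test_ratio_bounds_on_simulated_cohort(self, default_cell):
        """0 < a <= b and ratio in (0, 1] for every decomposable AP."""
        rec, _ = default_cell
        n_ok = n_total = 0
        for sweep in rec.depolarizing_sweeps():
            events = analyze_sweep(sweep)
            if not events:
                continue
            n_total += 1
            try:
                dec = slope_sd_ratio(sweep, events[0])
            except FeatureUndefined:
                continue
            n_ok += 1
            assert 0 < dec.a <= dec.b
            assert 0 < dec.slope_sd_ratio <= 1
            assert (dec.breakpoint.time > events[0].threshold_time)
        # breakpoint must be found on >= 95 % of first APs
        assert n_total > 0 and n_ok / n_total >= 0.95

    def test_voltage_offset_invariance(self, sigmoid_spike):
        sweep = sigmoid_spike.sweep()
        ev = _prepared_event(sweep)
        r0 = slope_sd_ratio(sweep, ev).slope_sd_ratio
        shifted = make_sweep_from_arrays(sweep.voltage + 12.0,
                                         sampling_rate=FS)
        ev2 = _prepared_event(shifted)
        r1 = slope_sd_ratio(shifted, ev2).slope_sd_ratio
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_time_rescaling_invariance(self):
        """Uniformly stretching the waveform in time scales a and b
        equally, leaving the ratio unchanged."""
        w_fast = two_sigmoid_spike(sigma=0.08, separation=0.6)
        w_slow = two_sigmoid_spike(sigma=0.16, separation=1.2)
        ratios = []
        for w in (w_fast, w_slow):
            sweep = w.sweep()
            ev = _prepared_event(sweep)
            ratios.append(slope_sd_ratio(sweep, ev).slope_sd_ratio)
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-3)

    def test_somatic_na_fraction_monotonicity(self, short_protocol):
        """Raising the somatic share of total Na conductance strictly
        raises the SD slope ratio."""
        total = 4500.0
        ratios = []
        for frac in (0.5, 0.8):
            p = NeuronParams(gna_soma=total * frac,
                             gna_ais=total * (1 - frac))
            rec, _ = simulate_cell(p, short_protocol, seed=3)
            sweep, ev, _ = first_ap_of_train(rec)
            ratios.append(slope_sd_ratio(sweep, ev).slope_sd_ratio)
        assert ratios[1] > ratios[0]


class TestFirstApOfTrain:
    def test_selects_first_spike_of_seven_train(self, default_cell):
        rec, _ = default_cell
        sweep, ev, approx = first_ap_of_train(rec)
        assert not approx
        events = analyze_sweep(sweep)
        assert len(events) == 7
        assert ev.peak_time == events[0].peak_time

    def test_no_spiking_undefined(self):
        from spikephase import CellRecording
        s = make_sweep_from_arrays(np.full(5000, -70.0), step_amplitude=100.0,
                                   step_onset=10.0, step_offset=90.0)
        rec = CellRecording(cell_id="c", sweeps=[s])
        with pytest.raises(FeatureUndefined):
            first_ap_of_train(rec)
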
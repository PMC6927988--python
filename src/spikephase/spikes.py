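"""Spike detection and single-AP / spike-train measurements.

Definitions implemented here:

* AP threshold: voltage at which dV/dt first reaches 20 V/s (20 mV/ms)
  on the upstroke, found by searching backward from the peak to the
  preceding sub-criterion region, with linear interpolation between the
  straddling samples.
* Half-width: AP duration at half amplitude above threshold,
  interpolated at both crossings.
* mAHP: threshold voltage minus the trough within 100 ms after the AP
  peak, truncated at the next spike's threshold or the step offset.
* Rheobase: smallest ladder current whose sweep contains >= 1 spike
  inside the step window; spike latency is measured on that sweep.
* Accommodation ratio: (ISI6 - ISI1)/ISI6 on a 7-spike train.

dV/dt uses central finite differences on the recorded trace (optionally
Savitzky-Golay pre-smoothed); all rates are reported in mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import CellRecording, Sweep
from .passive import FeatureUndefined

__all__ = [
    "APEvent",
    "TrainMetrics",
    "APFeatureSet",
    "dvdt",
    "second_derivative",
    "detect_spikes",
    "ap_threshold",
    "ap_shape",
    "ap_mahp",
    "find_rheobase",
    "find_n_spike_sweep",
    "isi_accommodation",
    "fi_curve",
    "extract_cell_features",
]

DVDT_CRITERION = 20.0     # mV/ms == 20 V/s
DETECTION_LEVEL = 0.0     # mV
MAHP_WINDOW_MS = 100.0


def dvdt(voltage: np.ndarray, dt_ms: float, smooth: bool = False,
         smooth_window: int = 5) -> np.ndarray:
    """First time derivative in mV/ms via central differences.

    Endpoints use one-sided differences.  ``smooth`` applies a
    Savitzky-Golay (order 2) pre-filter; off by default because typical
    input is already hardware-filtered.
    """
    v = np.asarray(voltage, dtype=float)
    if smooth and v.size >= smooth_window:
        v = savgol_filter(v, smooth_window, 2)
    return np.gradient(v, dt_ms)


def second_derivative(voltage: np.ndarray, dt_ms: float,
                      smooth: bool = False, smooth_window: int = 5) -> np.ndarray:
    """d2V/dt2 in mV/ms^2 via the direct three-point stencil."""
    v = np.asarray(voltage, dtype=float)
    if smooth and v.size >= smooth_window:
        v = savgol_filter(v, smooth_window, 2)
    d2 = np.empty_like(v)
    d2[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dt_ms**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


@dataclass
class APEvent:
    """One action potential's measurements (times in ms, voltages mV)."""

    index: int
    peak_index: int
    peak_time: float
    peak_voltage: float
    threshold_index: int = -1
    threshold_time: float = np.nan
    threshold_voltage: float = np.nan
    peak_amplitude: float = np.nan
    half_width: float = np.nan
    mahp: float = np.nan
    mahp_truncated: bool = False
    dvdt_max: float = np.nan
    dvdt_min: float = np.nan
    flags: dict = field(default_factory=dict)


@dataclass
class TrainMetrics:
    rheobase: float = np.nan
    rheobase_increment: float = np.nan
    spike_latency: float = np.nan
    n7_current: float = np.nan
    n7_count: int = 0
    n7_approximate: bool = False
    isi_1: float = np.nan
    isi_6: float = np.nan
    accommodation_ratio: float = np.nan
    fi_table: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


@dataclass
class APFeatureSet:
    """Per-cell bundle: rheobase-AP measurements plus train metrics."""

    cell_id: str
    rheobase_ap: APEvent | None
    train: TrainMetrics


def detect_spikes(
    sweep: Sweep,
    criterion: float = DETECTION_LEVEL,
    window: tuple[float, float] | None = None,
) -> list[APEvent]:
    """Detect APs as upward crossings of ``criterion`` followed by a
    local maximum.

    One event per supra-criterion excursion: the trace must fall back
    below the criterion before another AP can be counted (refractory
    guard), so merged depolarizations yield a single event.  ``window``
    optionally restricts detection to a (start_ms, end_ms) interval by
    peak time.
    """
    v = sweep.voltage
    above = v > criterion
    starts = np.flatnonzero(~above[:-1] & above[1:]) + 1
    ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    events = []
    for k, s in enumerate(starts):
        e_candidates = ends[ends > s]
        e = int(e_candidates[0]) if e_candidates.size else v.size
        peak = int(s + np.argmax(v[s:e]))
        t_peak = peak * sweep.dt
        if window is not None and not (window[0] <= t_peak < window[1]):
            continue
        events.append(APEvent(
            index=len(events), peak_index=peak, peak_time=t_peak,
            peak_voltage=float(v[peak]),
        ))
    return events


def ap_threshold(
    sweep: Sweep,
    event: APEvent,
    criterion: float = DVDT_CRITERION,
    interpolate: bool = True,
    search_start: int = 0,
    _dvdt: np.ndarray | None = None,
) -> float:
    """AP threshold: voltage where dV/dt first reaches ``criterion``
    mV/ms on the upstroke.

    Searches backward from the peak through the supra-criterion upstroke
    to the preceding sub-criterion sample; the crossing is linearly
    interpolated between the straddling samples unless ``interpolate``
    is False (then the first supra-criterion sample is used).

    Raises :class:`FeatureUndefined` if dV/dt never reaches the
    criterion before the peak — the event is not a spike.
    """
    d = dvdt(sweep.voltage, sweep.dt) if _dvdt is None else _dvdt
    i = event.peak_index
    # walk back to the supra-criterion upstroke
    while i > search_start and d[i] < criterion:
        i -= 1
    if d[i] < criterion:
        raise FeatureUndefined(
            f"dV/dt never reaches {criterion} mV/ms before the peak at "
            f"{event.peak_time:.3f} ms: not a spike"
        )
    # walk back to the preceding sub-criterion region
    while i > search_start and d[i - 1] >= criterion:
        i -= 1
    v = sweep.voltage
    if interpolate and i > search_start and d[i] != d[i - 1]:
        f = (criterion - d[i - 1]) / (d[i] - d[i - 1])
        thr_v = v[i - 1] + f * (v[i] - v[i - 1])
        thr_t = (i - 1 + f) * sweep.dt
    else:
        thr_v = float(v[i])
        thr_t = i * sweep.dt
    event.threshold_index = i
    event.threshold_time = float(thr_t)
    event.threshold_voltage = float(thr_v)
    return float(thr_v)


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_shape(
    sweep: Sweep,
    event: APEvent,
    end_index: int | None = None,
) -> APEvent:
    """Amplitude, half-width and dV/dt extrema for one AP.

    ``end_index`` bounds the spike window (next spike's threshold index
    or the step offset); defaults to the end of the sweep.
    """
    if not np.isfinite(event.threshold_voltage):
        raise FeatureUndefined("ap_shape requires a computed threshold")
    v = sweep.voltage
    end = v.size if end_index is None else min(end_index, v.size)
    event.peak_amplitude = event.peak_voltage - event.threshold_voltage
    half = event.threshold_voltage + event.peak_amplitude / 2.0

    t = sweep.dt
    # upward crossing of the half level between threshold and peak
    seg = np.flatnonzero(v[event.threshold_index:event.peak_index + 1] >= half)
    if seg.size == 0:
        event.flags["half_width"] = "no upward half-amplitude crossing"
        return event
    iu = event.threshold_index + seg[0]
    if iu > 0 and v[iu] != v[iu - 1]:
        t_up = _interp_crossing((iu - 1) * t, iu * t, v[iu - 1], v[iu], half)
    else:
        t_up = iu * t
    # downward crossing after the peak, before end
    seg = np.flatnonzero(v[event.peak_index:end] <= half)
    if seg.size == 0:
        event.half_width = np.nan
        event.flags["half_width"] = (
            "repolarization never recrosses half amplitude before the "
            "next spike / step end"
        )
    else:
        idn = event.peak_index + seg[0]
        if v[idn] != v[idn - 1]:
            t_dn = _interp_crossing((idn - 1) * t, idn * t, v[idn - 1], v[idn], half)
        else:
            t_dn = idn * t
        event.half_width = float(t_dn - t_up)

    d = dvdt(v, t)
    win = d[event.threshold_index:end]
    event.dvdt_max = float(np.max(win))
    event.dvdt_min = float(np.min(win))
    return event


def ap_mahp(
    sweep: Sweep,
    event: APEvent,
    next_event: APEvent | None = None,
    window_ms: float = MAHP_WINDOW_MS,
) -> float:
    """Medium afterhyperpolarization: threshold voltage minus the trough
    in (peak, peak + 100 ms], truncated at the next spike's threshold
    time or the step offset, whichever is earlier.  Truncation is
    recorded on the event."""
    if not np.isfinite(event.threshold_voltage):
        raise FeatureUndefined("mAHP requires a computed threshold")
    start = event.peak_index + 1
    t_end = event.peak_time + window_ms
    truncated = False
    if next_event is not None and np.isfinite(next_event.threshold_time):
        if next_event.threshold_time < t_end:
            t_end = next_event.threshold_time
            truncated = True
    if sweep.step_offset < t_end:
        t_end = sweep.step_offset
        truncated = True
    end = min(sweep.index_at(t_end) + 1, sweep.n_samples)
    if end <= start:
        event.flags["mahp"] = "empty mAHP window (spike at sweep end)"
        raise FeatureUndefined("empty mAHP search window")
    trough = float(np.min(sweep.voltage[start:end]))
    event.mahp = float(event.threshold_voltage - trough)
    event.mahp_truncated = truncated
    return event.mahp


def analyze_sweep(sweep: Sweep, window: tuple[float, float] | None = None
                  ) -> list[APEvent]:
    """Detect spikes in one sweep and fill in threshold, shape and mAHP
    for every event (per-event failures recorded in ``flags``)."""
    if window is None:
        window = (sweep.step_onset, sweep.step_offset)
    events = detect_spikes(sweep, window=window)
    d = dvdt(sweep.voltage, sweep.dt)
    kept = []
    for ev in events:
        start = kept[-1].peak_index if kept else 0
        try:
            ap_threshold(sweep, ev, search_start=start, _dvdt=d)
        except FeatureUndefined as e:
            ev.flags["threshold"] = str(e)
            continue
        kept.append(ev)
    for i, ev in enumerate(kept):
        ev.index = i
        nxt = kept[i + 1] if i + 1 < len(kept) else None
        end = nxt.threshold_index if nxt is not None else sweep.index_at(
            sweep.step_offset)
        end = max(end, ev.peak_index + 2)
        ap_shape(sweep, ev, end_index=end)
        try:
            ap_mahp(sweep, ev, next_event=nxt)
        except FeatureUndefined:
            pass
    return kept


def _spike_count(sweep: Sweep) -> int:
    return len(detect_spikes(
        sweep, window=(sweep.step_onset, sweep.step_offset)))


def find_rheobase(recording: CellRecording) -> tuple[float, float, Sweep]:
    """Smallest ladder current eliciting >= 1 spike.

    Returns (rheobase pA, spike latency ms, the rheobase sweep).  The
    latency is first-spike threshold time minus step onset.  Raises
    :class:`FeatureUndefined` if no sweep spikes.
    """
    depol = recording.depolarizing_sweeps()
    if not depol:
        raise FeatureUndefined("no depolarizing ladder: rheobase not computable")
    for sweep in depol:
        events = analyze_sweep(sweep)
        if events:
            latency = events[0].threshold_time - sweep.step_onset
            return float(sweep.step_amplitude), float(latency), sweep
    raise FeatureUndefined("no sweep contains a spike: rheobase not computable")


def find_n_spike_sweep(
    recording: CellRecording, n: int = 7
) -> tuple[Sweep, float, int, bool]:
    """The sweep with exactly ``n`` spikes at the smallest such current.

    If no sweep has exactly ``n`` spikes, the nearest count is used with
    a preference for counts below ``n`` on ties, and the result is
    flagged approximate.  Returns (sweep, current, count, approximate).
    """
    depol = recording.depolarizing_sweeps()
    counted = [(s, _spike_count(s)) for s in depol]
    spiking = [(s, c) for s, c in counted if c > 0]
    if not spiking:
        raise FeatureUndefined("no spiking sweep: n-spike train not available")
    exact = [(s, c) for s, c in spiking if c == n]
    if exact:
        sweep, c = min(exact, key=lambda sc: sc[0].step_amplitude)
        return sweep, float(sweep.step_amplitude), c, False
    # nearest count, preferring the one below n on ties, then lowest current
    sweep, c = min(
        spiking,
        key=lambda sc: (abs(sc[1] - n), sc[1] > n, sc[0].step_amplitude),
    )
    return sweep, float(sweep.step_amplitude), c, True


def isi_accommodation(spike_times_ms: np.ndarray) -> tuple[float, float, float]:
    """ISI1, ISI6 and the accommodation ratio (ISI6 - ISI1)/ISI6 from a
    train of >= 7 spikes (negative ratios are allowed)."""
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size < 7:
        raise FeatureUndefined(
            f"accommodation needs >= 7 spikes, got {t.size}"
        )
    isis = np.diff(t)
    isi_1 = float(isis[0])
    isi_6 = float(isis[5])
    return isi_1, isi_6, float((isi_6 - isi_1) / isi_6)


def fi_curve(recording: CellRecording, as_rate: bool = False) -> list[tuple[float, float]]:
    """(current pA, spike count) pairs over the depolarizing ladder,
    ordered by current.  ``as_rate`` divides by step duration (Hz)."""
    out = []
    for sweep in recording.depolarizing_sweeps():
        c = _spike_count(sweep)
        if as_rate:
            c = c / ((sweep.step_offset - sweep.step_onset) / 1000.0)
        out.append((float(sweep.step_amplitude), float(c)))
    return out


def extract_cell_features(recording: CellRecording, n_train: int = 7) -> APFeatureSet:
    """Rheobase-AP measurements plus train metrics for one cell."""
    train = TrainMetrics()
    rheo_ap = None
    depol = recording.depolarizing_sweeps()
    if len(depol) >= 2:
        incs = np.diff(sorted(s.step_amplitude for s in depol))
        train.rheobase_increment = float(np.min(incs))
    try:
        rheobase, latency, sweep = find_rheobase(recording)
        train.rheobase = rheobase
        train.spike_latency = latency
        events = analyze_sweep(sweep)
        rheo_ap = events[0] if events else None
        if depol and sweep.step_amplitude == min(
                s.step_amplitude for s in depol):
            train.flags["rheobase"] = "ladder-floor: lowest sweep already spikes"
    except FeatureUndefined as e:
        train.flags["rheobase"] = str(e)
    try:
        sweep7, cur7, count7, approx = find_n_spike_sweep(recording, n_train)
        train.n7_current = cur7
        train.n7_count = count7
        train.n7_approximate = approx
        events = analyze_sweep(sweep7)
        times = np.array([e.threshold_time for e in events])
        if times.size >= 7:
            train.isi_1, train.isi_6, train.accommodation_ratio = (
                isi_accommodation(times))
        else:
            train.flags["accommodation"] = (
                f"train has {times.size} analyzable spikes (< 7)")
    except FeatureUndefined as e:
        train.flags["n7"] = str(e)
    train.fi_table = fi_curve(recording)
    return APFeatureSet(cell_id=recording.cell_id, rheobase_ap=rheo_ap,
                        train=train)
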
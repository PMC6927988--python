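"""Phase-plot construction and AIS/SD decomposition of the AP rising phase.

The somatic AP upstroke of a pyramidal cell has two kinetically distinct
components: an axon-initial-segment (AIS) potential followed by the
somatodendritic (SD) potential.  Their breakpoint appears as a trough of
d2V/dt2 in the rising phase.  With

* ``b`` — peak dV/dt of the upstroke, and
* ``a`` — maximal slope of the SD component,

the SD slope ratio ``a/b`` indexes the perisomatic sodium contribution
to the upstroke, and ``b - a`` the AIS component.

The source figures mark ``a`` and ``b`` on the phase plot without an
equation, so two labeled conventions are provided:

* ``"b_minus_breakpoint"`` (default): ``a = b - dV/dt(breakpoint)`` —
  the SD contribution above the AIS shoulder, measured at the
  second-derivative trough.
* ``"ais_peak"``: ``a = b - max dV/dt over the AIS segment`` (threshold
  to breakpoint) — uses the AIS component's own maximum instead of the
  trough.

Every decomposition records the convention used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellRecording, Sweep
from .passive import FeatureUndefined
from .spikes import (
    APEvent,
    analyze_sweep,
    dvdt,
    find_n_spike_sweep,
    second_derivative,
)

__all__ = [
    "Breakpoint",
    "PhaseDecomposition",
    "phase_plot",
    "find_breakpoint",
    "slope_sd_ratio",
    "first_ap_of_train",
]

DEFAULT_CONVENTION = "b_minus_breakpoint"
MIN_RISING_SAMPLES = 4


@dataclass
class Breakpoint:
    index: int
    time: float          # ms
    voltage: float       # mV
    dvdt_value: float    # mV/ms
    d2v_value: float     # mV/ms^2
    prominence: float    # mV/ms^2, depth below the shallower neighbor peak


@dataclass
class PhaseDecomposition:
    voltage: np.ndarray
    dvdt: np.ndarray
    breakpoint: Breakpoint | None
    a: float
    b: float
    ais_component: float           # b - a
    slope_sd_ratio: float          # a / b
    convention: str
    flags: dict = field(default_factory=dict)


def phase_plot(sweep: Sweep, event: APEvent,
               smooth: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(V, dV/dt) samples for one AP, threshold to post-repolarization.

    The window runs from the threshold sample to the first
    re-crossing of the threshold voltage after the peak (or the sweep
    end).
    """
    if not np.isfinite(event.threshold_voltage):
        raise FeatureUndefined("phase plot requires a computed threshold")
    v = sweep.voltage
    d = dvdt(v, sweep.dt, smooth=smooth)
    below = np.flatnonzero(v[event.peak_index:] <= event.threshold_voltage)
    end = event.peak_index + (int(below[0]) + 1 if below.size else
                              v.size - event.peak_index)
    sl = slice(event.threshold_index, min(end + 1, v.size))
    return v[sl].copy(), d[sl].copy()


def find_breakpoint(
    sweep: Sweep,
    event: APEvent,
    smooth: bool = False,
    min_prominence: float = 0.0,
    _dvdt: np.ndarray | None = None,
) -> Breakpoint:
    """Locate the AIS/SD breakpoint of one AP.

    The breakpoint is the most negative strict local minimum of d2V/dt2
    strictly between the threshold time and the time of the dV/dt
    maximum — the curvature trough of the rising phase.  Raises
    :class:`FeatureUndefined` for a monophasic upstroke (no local
    minimum in the window) or a window shorter than
    ``MIN_RISING_SAMPLES``.
    """
    if not np.isfinite(event.threshold_voltage):
        raise FeatureUndefined("breakpoint search requires a computed threshold")
    v = sweep.voltage
    d = dvdt(v, sweep.dt, smooth=smooth) if _dvdt is None else _dvdt
    i0 = event.threshold_index
    i_b = i0 + int(np.argmax(d[i0:event.peak_index + 1]))
    if i_b - i0 < MIN_RISING_SAMPLES:
        raise FeatureUndefined(
            f"rising phase spans {i_b - i0} samples "
            f"(< {MIN_RISING_SAMPLES}): too short to decompose"
        )
    d2 = second_derivative(v, sweep.dt, smooth=smooth)
    seg = d2[i0 + 1:i_b]          # strictly between threshold and dV/dt max
    if seg.size < 3:
        raise FeatureUndefined("rising-phase window too short for a local minimum")
    interior = np.flatnonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:])) + 1
    if interior.size == 0:
        raise FeatureUndefined(
            "monophasic upstroke: no d2V/dt2 local minimum between "
            "threshold and the dV/dt maximum"
        )
    best = interior[np.argmin(seg[interior])]
    idx = i0 + 1 + int(best)
    # prominence: rise to the lower of the two flanking maxima
    left_peak = np.max(seg[:best + 1])
    right_peak = np.max(seg[best:])
    prom = float(min(left_peak, right_peak) - seg[best])
    if prom < min_prominence:
        raise FeatureUndefined(
            f"d2V/dt2 trough prominence {prom:.1f} below the configured "
            f"minimum {min_prominence}"
        )
    return Breakpoint(
        index=idx,
        time=idx * sweep.dt,
        voltage=float(v[idx]),
        dvdt_value=float(d[idx]),
        d2v_value=float(d2[idx]),
        prominence=prom,
    )


def slope_sd_ratio(
    sweep: Sweep,
    event: APEvent,
    convention: str = DEFAULT_CONVENTION,
    smooth: bool = False,
    min_prominence: float = 0.0,
) -> PhaseDecomposition:
    """Decompose the AP upstroke into AIS and SD slope components.

    ``b`` is the peak dV/dt of the upstroke; ``a`` follows the chosen
    convention (module docstring).  Raises :class:`FeatureUndefined`
    when the breakpoint is undefined.
    """
    v_ph, d_ph = phase_plot(sweep, event, smooth=smooth)
    d = dvdt(sweep.voltage, sweep.dt, smooth=smooth)
    bp = find_breakpoint(sweep, event, smooth=smooth,
                         min_prominence=min_prominence, _dvdt=d)
    i0 = event.threshold_index
    b = float(np.max(d[i0:event.peak_index + 1]))
    if convention == "b_minus_breakpoint":
        shoulder = bp.dvdt_value
    elif convention == "ais_peak":
        shoulder = float(np.max(d[i0:bp.index + 1]))
    else:
        raise ValueError(
            f"unknown convention {convention!r} "
            "(use 'b_minus_breakpoint' or 'ais_peak')"
        )
    a = b - shoulder
    return PhaseDecomposition(
        voltage=v_ph, dvdt=d_ph, breakpoint=bp,
        a=a, b=b, ais_component=b - a,
        slope_sd_ratio=a / b, convention=convention,
    )


def first_ap_of_train(
    recording: CellRecording, n: int = 7
) -> tuple[Sweep, APEvent, bool]:
    """First AP of the n-spike train that feeds the SD slope ratio.

    Returns (sweep, event, approximate) where ``approximate`` is True
    when no sweep had exactly ``n`` spikes and the nearest-count
    fallback was used.
    """
    sweep, _cur, _count, approx = find_n_spike_sweep(recording, n)
    events = analyze_sweep(sweep)
    if not events:
        raise FeatureUndefined("train sweep has no analyzable spikes")
    return sweep, events[0], approx
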
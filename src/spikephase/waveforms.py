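"""Analytic synthetic waveforms for validating the extractors.

These constructions have closed-form derivatives, so every quantity the
extractors estimate from sampled data (threshold crossing, breakpoint,
slope components) can be computed exactly and independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .io import Sweep

__all__ = ["TwoSigmoidSpike", "two_sigmoid_spike"]


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _dsig(x):
    s = _sig(x)
    return s * (1.0 - s)


def _d2sig(x):
    s = _sig(x)
    return s * (1.0 - s) * (1.0 - 2.0 * s)


@dataclass
class TwoSigmoidSpike:
    """A biphasic AP upstroke built as the sum of two time-shifted
    sigmoids (AIS component then SD component), with every analytic
    reference quantity solved from the closed-form derivatives.

    ``V(t) = v0 + a1*sig((t-t1)/s1) + a2*sig((t-t2)/s2)``; the maximal
    slope of component i is ``a_i / (4 s_i)``.
    """

    a1: float
    s1: float
    t1: float
    a2: float
    s2: float
    t2: float
    v0: float
    sampling_rate: float
    duration: float
    # analytic reference values
    threshold_time: float
    threshold_voltage: float
    peak_slope_time: float
    peak_slope: float               # b
    breakpoint_time: float          # argmin d2V/dt2 in the rising phase
    breakpoint_slope: float         # dV/dt there
    sd_ratio: float                 # (b - breakpoint_slope) / b
    ais_peak_slope: float           # max slope of the AIS component alone

    def voltage(self, t):
        return (self.v0 + self.a1 * _sig((t - self.t1) / self.s1)
                + self.a2 * _sig((t - self.t2) / self.s2))

    def slope(self, t):
        return (self.a1 / self.s1 * _dsig((t - self.t1) / self.s1)
                + self.a2 / self.s2 * _dsig((t - self.t2) / self.s2))

    def curvature(self, t):
        return (self.a1 / self.s1**2 * _d2sig((t - self.t1) / self.s1)
                + self.a2 / self.s2**2 * _d2sig((t - self.t2) / self.s2))

    def sweep(self, sampling_rate: float | None = None) -> Sweep:
        fs = sampling_rate or self.sampling_rate
        t = np.arange(0.0, self.duration, 1000.0 / fs)
        return Sweep(
            voltage=self.voltage(t), current=np.zeros_like(t),
            sampling_rate=fs, step_amplitude=0.0,
            step_onset=0.0, step_offset=self.duration,
        )


def two_sigmoid_spike(
    ais_peak_slope: float = 100.0,
    sd_peak_slope: float = 400.0,
    sigma: float = 0.08,
    separation: float = 0.6,
    threshold_voltage: float = -34.0,
    threshold_criterion: float = 20.0,
    t1: float = 10.0,
    sampling_rate: float = 50_000.0,
    duration: float = 20.0,
) -> TwoSigmoidSpike:
    """Build a two-sigmoid upstroke with designed slope components.

    ``ais_peak_slope``/``sd_peak_slope`` are each component's maximal
    slope (mV/ms); the baseline offset is solved so that the combined
    slope crosses ``threshold_criterion`` exactly at
    ``threshold_voltage``.  All reference quantities (threshold
    crossing, slope maximum ``b``, curvature-trough location and the
    slope there) are solved from the analytic derivatives with
    root-finding / bounded minimization, independent of any sampled
    representation.
    """
    a1 = 4.0 * sigma * ais_peak_slope
    a2 = 4.0 * sigma * sd_peak_slope
    t2 = t1 + separation
    w = TwoSigmoidSpike(
        a1=a1, s1=sigma, t1=t1, a2=a2, s2=sigma, t2=t2, v0=0.0,
        sampling_rate=sampling_rate, duration=duration,
        threshold_time=np.nan, threshold_voltage=np.nan,
        peak_slope_time=np.nan, peak_slope=np.nan,
        breakpoint_time=np.nan, breakpoint_slope=np.nan, sd_ratio=np.nan,
        ais_peak_slope=ais_peak_slope,
    )
    t_cross = brentq(lambda t: w.slope(t) - threshold_criterion,
                     t1 - 20.0 * sigma, t1)
    w.v0 = threshold_voltage - w.voltage(t_cross)
    w.threshold_time = t_cross
    w.threshold_voltage = threshold_voltage
    res = minimize_scalar(lambda t: -w.slope(t), bounds=(t2 - 5 * sigma,
                          t2 + 5 * sigma), method="bounded")
    w.peak_slope_time = float(res.x)
    w.peak_slope = float(-res.fun)
    res = minimize_scalar(w.curvature, bounds=(t_cross, w.peak_slope_time),
                          method="bounded")
    w.breakpoint_time = float(res.x)
    w.breakpoint_slope = float(w.slope(w.breakpoint_time))
    w.sd_ratio = (w.peak_slope - w.breakpoint_slope) / w.peak_slope
    return w
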
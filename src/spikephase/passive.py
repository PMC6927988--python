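"""Passive and subthreshold measurements.

Resting membrane potential (RMP), input resistance (Rin), sag ratio and
the prominent-H-current classification.  Conventions:

* RMP: mean voltage over a zero-current epoch — a zero-amplitude sweep
  if present, otherwise the pre-step baseline window (default 50 ms
  immediately before step onset).
* Rin: steady-state dV/dI from the hyperpolarizing step nearest -100 pA
  (default), or the slope of a dV-I line over all hyperpolarizing sweeps
  (``method="fit"``).  Steady state = mean over the final 20 % of the
  step.
* Sag ratio = (|peak| - |steady-state|) / |peak| of the hyperpolarizing
  deflection from baseline; cells with sag ratio > 5 % are classified as
  having a prominent H-current (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CellRecording, Sweep

__all__ = [
    "FeatureUndefined",
    "PassiveFeatures",
    "resting_potential",
    "input_resistance",
    "sag_ratio",
    "classify_h_current",
    "passive_features",
]

#: voltage above which a "baseline" sample is treated as spike contamination
CONTAMINATION_MV = -20.0
PROMINENT_H_THRESHOLD = 0.05


class FeatureUndefined(ValueError):
    """The requested measurement is not computable from this recording."""


@dataclass
class PassiveFeatures:
    rmp: float
    input_resistance: float
    sag: float
    prominent_h: bool | None
    baseline_window_ms: float
    steady_fraction: float
    flags: dict


def _baseline_window(sweep: Sweep, window_ms: float) -> np.ndarray:
    end = sweep.index_at(sweep.step_onset)
    start = max(0, end - int(round(window_ms * sweep.sampling_rate / 1000.0)))
    if end <= start:
        raise FeatureUndefined("no pre-step baseline available")
    return sweep.voltage[start:end]


def resting_potential(
    recording: CellRecording, window_ms: float = 50.0
) -> float:
    """Mean membrane voltage (mV) while no current is injected.

    Raises :class:`FeatureUndefined` if no zero-current epoch exists or
    if the chosen window contains spike contamination (any sample above
    -20 mV).
    """
    zero = [s for s in recording.sweeps if s.step_amplitude == 0]
    if zero:
        seg = zero[0].voltage
    else:
        candidates = [s for s in recording.sweeps if s.step_onset > 0]
        if not candidates:
            raise FeatureUndefined(
                "no zero-current epoch: no zero-amplitude sweep and no "
                "pre-step baseline"
            )
        seg = _baseline_window(candidates[0], window_ms)
    if np.max(seg) > CONTAMINATION_MV:
        raise FeatureUndefined(
            "baseline window contains spike contamination "
            f"(max {np.max(seg):.1f} mV > {CONTAMINATION_MV} mV)"
        )
    return float(np.mean(seg))


def _steady_deflection(
    sweep: Sweep, window_ms: float, steady_fraction: float
) -> tuple[float, float]:
    """(baseline mV, steady-state mV) for one step sweep."""
    base = float(np.mean(_baseline_window(sweep, window_ms)))
    off = sweep.index_at(sweep.step_offset)
    on = sweep.index_at(sweep.step_onset)
    w = max(1, int(round((off - on) * steady_fraction)))
    steady = float(np.mean(sweep.voltage[off - w:off]))
    return base, steady


def input_resistance(
    recording: CellRecording,
    method: str = "step",
    target_amplitude: float = -100.0,
    window_ms: float = 50.0,
    steady_fraction: float = 0.2,
) -> float:
    """Input resistance in MOhm from hyperpolarizing step responses.

    ``method="step"``: steady-state dV/dI on the sweep whose amplitude
    is nearest ``target_amplitude``.  ``method="fit"``: slope of the
    least-squares dV-I line over all hyperpolarizing sweeps (requires
    >= 2; falls back to the single-step estimate for 1).
    """
    hyper = recording.hyperpolarizing_sweeps()
    if not hyper:
        raise FeatureUndefined("no hyperpolarizing sweep: Rin not computable")
    if method == "step" or len(hyper) == 1:
        sweep = min(hyper, key=lambda s: abs(s.step_amplitude - target_amplitude))
        base, steady = _steady_deflection(sweep, window_ms, steady_fraction)
        dv = steady - base                      # mV
        di = sweep.step_amplitude               # pA
        return float(dv / di * 1000.0)          # mV/pA = GOhm -> MOhm
    if method == "fit":
        dvs, dis = [], []
        for sweep in hyper:
            base, steady = _steady_deflection(sweep, window_ms, steady_fraction)
            dvs.append(steady - base)
            dis.append(sweep.step_amplitude)
        slope = np.polyfit(dis, dvs, 1)[0]
        return float(slope * 1000.0)
    raise ValueError(f"unknown Rin method {method!r} (use 'step' or 'fit')")


def sag_ratio(
    sweep: Sweep, window_ms: float = 50.0, steady_fraction: float = 0.2
) -> float:
    """Sag ratio of a hyperpolarizing step response.

    Peak = most hyperpolarized deflection from baseline during the step;
    steady state = mean deflection over the final ``steady_fraction`` of
    the step; sag = (|peak| - |steady|) / |peak|.
    """
    if sweep.step_amplitude >= 0:
        raise FeatureUndefined(
            f"sag requires a hyperpolarizing step, got {sweep.step_amplitude} pA"
        )
    base, steady = _steady_deflection(sweep, window_ms, steady_fraction)
    on = sweep.index_at(sweep.step_onset)
    off = sweep.index_at(sweep.step_offset)
    peak = float(np.min(sweep.voltage[on:off])) - base
    steady_defl = steady - base
    if peak >= 0:
        raise FeatureUndefined("no hyperpolarizing deflection found during the step")
    return float((abs(peak) - abs(steady_defl)) / abs(peak))


def classify_h_current(sag: float) -> bool:
    """Prominent H-current iff sag ratio strictly exceeds 5 %."""
    if not np.isfinite(sag):
        raise FeatureUndefined("sag ratio is undefined")
    return bool(sag > PROMINENT_H_THRESHOLD)


def prominent_fraction_percent(n_prominent: int, n_total: int) -> float:
    """Percentage of cells classified prominent-H, rounded to one
    decimal as reported in group summaries (e.g. 19/35 -> 54.3)."""
    if n_total < 1 or not 0 <= n_prominent <= n_total:
        raise ValueError("need 0 <= n_prominent <= n_total, n_total >= 1")
    return round(100.0 * n_prominent / n_total, 1)


def passive_features(
    recording: CellRecording,
    window_ms: float = 50.0,
    steady_fraction: float = 0.2,
    rin_method: str = "step",
) -> PassiveFeatures:
    """All passive measurements for one cell; non-computable ones are NaN
    with an explanatory entry in ``flags``."""
    flags: dict = {}
    try:
        rmp = resting_potential(recording, window_ms)
    except FeatureUndefined as e:
        rmp, flags["rmp"] = np.nan, str(e)
    try:
        rin = input_resistance(recording, method=rin_method,
                               window_ms=window_ms,
                               steady_fraction=steady_fraction)
    except FeatureUndefined as e:
        rin, flags["input_resistance"] = np.nan, str(e)
    sag = np.nan
    prominent: bool | None = None
    hyper = recording.hyperpolarizing_sweeps()
    if hyper:
        sweep = min(hyper, key=lambda s: abs(s.step_amplitude + 100.0))
        try:
            sag = sag_ratio(sweep, window_ms, steady_fraction)
            prominent = classify_h_current(sag)
        except FeatureUndefined as e:
            flags["sag"] = str(e)
    else:
        flags["sag"] = "no hyperpolarizing sweep"
    return PassiveFeatures(
        rmp=rmp, input_resistance=rin, sag=sag, prominent_h=prominent,
        baseline_window_ms=window_ms, steady_fraction=steady_fraction,
        flags=flags,
    )
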
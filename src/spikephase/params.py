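"""Parameter containers for the synthetic-trace simulator.

The simulator is a two-compartment (soma + axon initial segment)
conductance-based model.  Conductances are whole-cell values in nS,
capacitances in pF, voltages in mV, times in ms — so ``g * V`` is in pA
and ``C * dV/dt`` is in pA without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

__all__ = ["NeuronParams", "ProtocolSpec"]


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of the two-compartment model neuron.

    The axon initial segment (AIS) carries a low-threshold sodium
    conductance (Nav1.6-like) whose activation midpoint sits
    ``na_halfact_shift`` mV below the somatic (Nav1.2-like) midpoint, so
    the AIS fires first and the somatic action potential rises in two
    kinetically distinct components.

    Attributes
    ----------
    leak_conductance : float
        Somatic leak, nS.  Sets the passive input resistance,
        Rin = 1000 / leak_conductance MOhm.
    leak_reversal : float
        Leak reversal potential, mV.  Equals the resting potential when
        every active conductance is zero.
    capacitance_soma, capacitance_ais : float
        Compartment capacitances, pF.
    axial_conductance : float
        Soma-AIS coupling conductance, nS.
    gna_soma, gna_ais : float
        Maximal sodium conductances, nS.  The somatic/AIS balance sets
        the relative size of the somatodendritic (SD) and AIS components
        of the AP upstroke.
    na_halfact_soma : float
        Somatic Na activation midpoint, mV.
    na_halfact_shift : float
        AIS activation midpoint minus somatic midpoint, mV; must be
        strictly negative (AIS more hyperpolarized).
    gk_dr : float
        Delayed-rectifier potassium conductance, nS (somatic; a fixed
        fraction is placed in the AIS, see the simulator).
    gsk : float
        SK-type calcium-activated potassium conductance, nS, driven by a
        phenomenological per-spike calcium pool.  Sets the medium
        afterhyperpolarization (mAHP) and spike-train accommodation.
    ca_increment : float
        Dimensionless calcium-pool increment added at each spike.
    ca_tau : float
        Calcium-pool decay time constant, ms.
    gh : float
        HCN-like (H-current) conductance, nS.  Produces the
        hyperpolarization-activated sag.
    gh_tau : float
        H-current activation time constant, ms.
    noise_sd : float
        Approximate standard deviation of resting membrane-voltage
        noise, mV (Ornstein-Uhlenbeck current noise; 0 disables it and
        makes traces fully deterministic).
    """

    leak_conductance: float = 4.8
    leak_reversal: float = -70.0
    capacitance_soma: float = 150.0
    capacitance_ais: float = 6.0
    axial_conductance: float = 120.0
    gna_soma: float = 3600.0
    gna_ais: float = 900.0
    na_halfact_soma: float = -26.0
    na_halfact_shift: float = -10.0
    gk_dr: float = 500.0
    gsk: float = 12.0
    ca_increment: float = 1.0
    ca_tau: float = 60.0
    gh: float = 1.6
    gh_tau: float = 50.0
    noise_sd: float = 0.0

    def validate(self) -> None:
        for name in (
            "leak_conductance", "axial_conductance", "gna_soma", "gna_ais",
            "gk_dr", "gsk", "gh", "noise_sd", "ca_increment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("capacitance_soma", "capacitance_ais", "ca_tau", "gh_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.na_halfact_shift < 0:
            raise ValueError(
                "na_halfact_shift must be strictly negative: the AIS sodium "
                "activation midpoint sits below the somatic one "
                f"(got {self.na_halfact_shift})"
            )
        for name in ("leak_reversal", "na_halfact_soma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_(self, **kwargs) -> "NeuronParams":
        """Return a copy with the given fields replaced (and validated)."""
        p = replace(self, **kwargs)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def input_resistance_true(self) -> float:
        """Leak-implied passive input resistance, MOhm."""
        return 1000.0 / self.leak_conductance

    @property
    def somatic_na_fraction(self) -> float:
        """gna_soma / (gna_soma + gna_ais); the dial behind the SD slope ratio."""
        return self.gna_soma / (self.gna_soma + self.gna_ais)


@dataclass(frozen=True)
class ProtocolSpec:
    """A family of square current-step sweeps.

    The default mirrors a standard intrinsic-excitability protocol:
    50 kHz sampling, depolarizing steps from 50 to 1,500 pA plus one
    -100 pA hyperpolarizing step.
    """

    step_amplitudes: tuple = field(default_factory=tuple)
    step_onset: float = 100.0       # ms
    step_duration: float = 500.0    # ms
    post_baseline: float = 150.0    # ms
    sampling_rate: float = 50_000.0  # Hz

    @property
    def pre_baseline(self) -> float:
        return self.step_onset

    @property
    def total_duration(self) -> float:
        return self.step_onset + self.step_duration + self.post_baseline

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate / 1000.0))

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.step_onset < 0 or self.step_duration <= 0 or self.post_baseline < 0:
            raise ValueError("step timing must be non-negative with positive duration")
        if not self.step_amplitudes:
            raise ValueError("protocol has no step amplitudes")
        amps = np.asarray(self.step_amplitudes, dtype=float)
        if not np.all(np.isfinite(amps)):
            raise ValueError("step amplitudes must be finite")

    @classmethod
    def default_ladder(
        cls,
        start: float = 50.0,
        stop: float = 1500.0,
        increment: float = 50.0,
        hyperpolarizing: float | None = -100.0,
        **kwargs,
    ) -> "ProtocolSpec":
        """Hyperpolarizing step followed by a depolarizing ladder."""
        amps: list[float] = []
        if hyperpolarizing is not None:
            amps.append(float(hyperpolarizing))
        amps.extend(np.arange(start, stop + increment / 2, increment).tolist())
        return cls(step_amplitudes=tuple(amps), **kwargs)

    def command_waveform(self, amplitude: float) -> np.ndarray:
        """Command-current series (pA) for one sweep at sample resolution."""
        i = np.zeros(self.n_samples)
        dt_ms = 1000.0 / self.sampling_rate
        on = int(round(self.step_onset / dt_ms))
        off = int(round(self.step_offset / dt_ms))
        i[on:off] = amplitude
        return i
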
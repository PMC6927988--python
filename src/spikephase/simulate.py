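"""Two-compartment conductance-based synthetic-trace simulator.

The model couples a somatic and an axon-initial-segment (AIS)
compartment through an axial conductance.  The AIS carries a
low-threshold sodium conductance (Nav1.6-like) and the soma a
high-threshold one (Nav1.2-like); because the AIS activation midpoint is
more hyperpolarized, spikes initiate there and invade the soma, so the
somatic AP rising phase has two kinetically distinct components — an
AIS-driven shoulder followed by the somatodendritic (SD) upstroke —
visible as a trough in d2V/dt2.  An SK-like conductance driven by a
phenomenological per-spike calcium pool produces the medium
afterhyperpolarization and spike-train accommodation; an HCN-like
conductance produces the hyperpolarization-activated sag.

Kinetics (documented here because they are the package's own choice, not
taken from any recording hardware):

* Na: ``g m^3 h (V - 60)``; ``m_inf = 1/(1+exp(-(V-vh)/6))``,
  ``tau_m = 0.08`` ms; ``h_inf = 1/(1+exp((V-vh+10)/10))`` (inactivation
  midpoint = activation midpoint - 10 mV, slope 10 mV — shallow enough
  that sodium stays partly available during the slow approach to
  threshold), ``tau_h(V) = 0.4 + 4.5/(1+exp((V+40)/6))`` ms.  AIS
  activation midpoint = somatic + ``na_halfact_shift``.
* K (delayed rectifier): ``g n^2 (V + 90)``;
  ``n_inf = 1/(1+exp(-(V+20)/10))``, ``tau_n = 1.2`` ms.  A fixed 15 % of
  ``gk_dr`` is placed in the AIS.  The AIS carries no leak of its own, so
  the passive (all-active-conductances-zero) input resistance is exactly
  ``1/leak_conductance`` and the passive resting potential is exactly the
  leak reversal.
* SK: ``gsk c (V + 90)`` with pool ``c`` incremented by ``ca_increment``
  at each somatic spike (upward crossing of 0 mV) and decaying with
  ``ca_tau``.
* H: ``gh r (V + 30)``; ``r_inf = 1/(1+exp((V+82)/9))``, ``tau_r = gh_tau``.

Integration is fixed-step semi-implicit (exponential Euler for gates,
implicit-in-V for the membrane equation) at ``substeps`` sub-intervals
per output sample, with a 300 ms unrecorded settling period before each
sweep and a finiteness check on every sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import CellRecording, Sweep
from .params import NeuronParams, ProtocolSpec

__all__ = [
    "GroundTruth",
    "CohortGroundTruth",
    "SimulationError",
    "simulate_cell",
    "simulate_cohort",
]

E_NA = 60.0    # mV
E_K = -90.0    # mV
E_H = -30.0    # mV
NA_INACT_OFFSET = -10.0   # inactivation midpoint relative to activation midpoint
AIS_K_FRACTION = 0.15     # share of gk_dr placed in the AIS
SPIKE_CRITERION_MV = 0.0  # ground-truth spike time = upward crossing of this level
SETTLE_MS = 300.0
NOISE_TAU_MS = 5.0


class SimulationError(RuntimeError):
    """The integrator produced a non-finite voltage for a parameter set."""


@dataclass
class GroundTruth:
    """What the simulator knows that an extractor must recover."""

    params: NeuronParams
    protocol: ProtocolSpec
    seed: int
    spike_times: list = field(default_factory=list)  # one array (ms) per sweep

    @property
    def rin_true(self) -> float:
        """Leak-implied input resistance, MOhm."""
        return self.params.input_resistance_true

    @property
    def rmp_proxy(self) -> float:
        """Leak reversal, mV (equals RMP when all active conductances are 0)."""
        return self.params.leak_reversal

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "seed": self.seed,
            "rin_true_mohm": self.rin_true,
            "rmp_proxy_mv": self.rmp_proxy,
            "spike_times_ms": [list(map(float, t)) for t in self.spike_times],
        }


@dataclass
class CohortGroundTruth:
    per_cell_params: list
    seed: int
    clipped_fields: list = field(default_factory=list)


@njit(cache=True)
def _run_sweep(i_cmd, dt, substeps, seed, use_noise,
               g_leak, e_leak, c_soma, c_ais, g_ax,
               gna_s, gna_a, vh_m_s, vh_m_a,
               gk, gsk, ca_inc, ca_tau, gh, gh_tau, noise_sd):
    """Integrate one sweep; returns (v_soma, v_ais, spike_times_ms)."""
    np.random.seed(seed)
    n = i_cmd.size
    h_dt = dt / substeps  # ms

    gk_a = AIS_K_FRACTION * gk
    vh_h_s = vh_m_s + NA_INACT_OFFSET
    vh_h_a = vh_m_a + NA_INACT_OFFSET
    tau_m = 0.08
    tau_n = 1.2

    em_m = 1.0 - np.exp(-h_dt / tau_m)
    em_n = 1.0 - np.exp(-h_dt / tau_n)
    em_c = 1.0 - np.exp(-h_dt / ca_tau)
    em_r = 1.0 - np.exp(-h_dt / gh_tau)

    # OU current noise scaled so resting voltage sd is ~ noise_sd
    sigma_i = noise_sd * g_leak * np.sqrt(1.0 + NOISE_TAU_MS / (c_soma / g_leak))
    ou_decay = np.exp(-h_dt / NOISE_TAU_MS)
    ou_kick = sigma_i * np.sqrt(1.0 - ou_decay * ou_decay)

    vs = e_leak
    va = e_leak
    m_s = 1.0 / (1.0 + np.exp(-(vs - vh_m_s) / 6.0))
    h_s = 1.0 / (1.0 + np.exp((vs - vh_h_s) / 10.0))
    m_a = 1.0 / (1.0 + np.exp(-(va - vh_m_a) / 6.0))
    h_a = 1.0 / (1.0 + np.exp((va - vh_h_a) / 10.0))
    n_s = 1.0 / (1.0 + np.exp(-(vs + 20.0) / 10.0))
    n_a = n_s
    r = 1.0 / (1.0 + np.exp((vs + 82.0) / 9.0))
    ca = 0.0
    i_ou = 0.0

    v_soma = np.empty(n)
    v_ais = np.empty(n)
    spike_times = []
    above = vs > SPIKE_CRITERION_MV

    n_settle = int(SETTLE_MS / h_dt)
    total = n_settle + n * substeps
    for step in range(total):
        recording = step >= n_settle
        if recording:
            k = step - n_settle
            samp = k // substeps
            i_inj = i_cmd[samp]
        else:
            i_inj = 0.0

        # gates: exponential Euler at the current voltages
        m_s += (1.0 / (1.0 + np.exp(-(vs - vh_m_s) / 6.0)) - m_s) * em_m
        tau_h_s = 0.4 + 4.5 / (1.0 + np.exp((vs + 40.0) / 6.0))
        h_s += ((1.0 / (1.0 + np.exp((vs - vh_h_s) / 10.0)) - h_s)
                * (1.0 - np.exp(-h_dt / tau_h_s)))
        m_a += (1.0 / (1.0 + np.exp(-(va - vh_m_a) / 6.0)) - m_a) * em_m
        tau_h_a = 0.4 + 4.5 / (1.0 + np.exp((va + 40.0) / 6.0))
        h_a += ((1.0 / (1.0 + np.exp((va - vh_h_a) / 10.0)) - h_a)
                * (1.0 - np.exp(-h_dt / tau_h_a)))
        n_s += (1.0 / (1.0 + np.exp(-(vs + 20.0) / 10.0)) - n_s) * em_n
        n_a += (1.0 / (1.0 + np.exp(-(va + 20.0) / 10.0)) - n_a) * em_n
        r += (1.0 / (1.0 + np.exp((vs + 82.0) / 9.0)) - r) * em_r
        ca -= ca * em_c

        if use_noise:
            i_ou = ou_decay * i_ou + ou_kick * np.random.randn()

        # soma: semi-implicit update (conductances frozen within the substep)
        gna_eff = gna_s * m_s * m_s * m_s * h_s
        gk_eff = gk * n_s * n_s
        gsk_eff = gsk * ca
        gh_eff = gh * r
        g_tot = g_leak + gna_eff + gk_eff + gsk_eff + gh_eff + g_ax
        num = (g_leak * e_leak + gna_eff * E_NA + gk_eff * E_K + gsk_eff * E_K
               + gh_eff * E_H + g_ax * va + i_inj + i_ou)
        vs_new = (vs + (h_dt / c_soma) * num) / (1.0 + (h_dt / c_soma) * g_tot)

        # AIS
        gna_eff_a = gna_a * m_a * m_a * m_a * h_a
        gk_eff_a = gk_a * n_a * n_a
        g_tot_a = gna_eff_a + gk_eff_a + g_ax
        num_a = gna_eff_a * E_NA + gk_eff_a * E_K + g_ax * vs
        va_new = (va + (h_dt / c_ais) * num_a) / (1.0 + (h_dt / c_ais) * g_tot_a)

        # somatic spike detection: upward crossing of the criterion level
        if recording and (not above) and vs_new > SPIKE_CRITERION_MV:
            frac = (SPIKE_CRITERION_MV - vs) / (vs_new - vs)
            t_ms = (step - n_settle + frac) * h_dt
            spike_times.append(t_ms)
            ca += ca_inc
        above = vs_new > SPIKE_CRITERION_MV

        vs = vs_new
        va = va_new

        if recording and (step - n_settle) % substeps == substeps - 1:
            samp = (step - n_settle) // substeps
            v_soma[samp] = vs
            v_ais[samp] = va

    out_times = np.empty(len(spike_times))
    for i in range(len(spike_times)):
        out_times[i] = spike_times[i]
    return v_soma, v_ais, out_times


def simulate_cell(
    params: NeuronParams,
    protocol: ProtocolSpec,
    seed: int = 0,
    substeps: int = 4,
    cell_id: str = "sim",
    group: str = "",
) -> tuple[CellRecording, GroundTruth]:
    """Simulate one cell through a step protocol.

    Returns the recording (one sweep per step amplitude, in protocol
    order) and the ground truth: the generating parameters and the exact
    somatic spike times (upward crossings of 0 mV, linearly interpolated
    between integrator substeps).

    With ``params.noise_sd == 0`` the output is fully deterministic;
    otherwise each sweep uses an independent substream derived from
    ``seed``.

    Raises
    ------
    SimulationError
        If the integrator produces a non-finite voltage (reported with
        the offending parameter set).
    ValueError
        If the protocol has no steps or either input violates its
        invariants.
    """
    params.validate()
    protocol.validate()
    dt = 1000.0 / protocol.sampling_rate
    p = params
    use_noise = p.noise_sd > 0
    sweeps = []
    spike_times = []
    for k, amp in enumerate(protocol.step_amplitudes):
        i_cmd = protocol.command_waveform(amp)
        sweep_seed = (int(seed) * 100003 + k * 7919) % (2**31 - 1)
        vh_s = p.na_halfact_soma
        vh_a = p.na_halfact_soma + p.na_halfact_shift
        v_soma, _v_ais, times = _run_sweep(
            i_cmd, dt, substeps, sweep_seed, use_noise,
            p.leak_conductance, p.leak_reversal, p.capacitance_soma,
            p.capacitance_ais, p.axial_conductance,
            p.gna_soma, p.gna_ais, vh_s, vh_a,
            p.gk_dr, p.gsk, p.ca_increment, p.ca_tau, p.gh, p.gh_tau,
            p.noise_sd,
        )
        if not np.all(np.isfinite(v_soma)):
            raise SimulationError(
                f"non-finite voltage on sweep {k} (step {amp} pA) "
                f"with params {p.to_dict()}"
            )
        sweeps.append(Sweep(
            voltage=v_soma,
            current=i_cmd,
            sampling_rate=protocol.sampling_rate,
            step_amplitude=float(amp),
            step_onset=protocol.step_onset,
            step_offset=protocol.step_offset,
        ))
        spike_times.append(times)
    rec = CellRecording(cell_id=cell_id, sweeps=sweeps, group=group)
    truth = GroundTruth(params=params, protocol=protocol, seed=int(seed),
                        spike_times=spike_times)
    return rec, truth


#: documented parameter grid for the dial-monotonicity checks:
#: sag must increase along the gh axis, mAHP along the gsk axis, and the
#: SD slope ratio along the somatic-Na-fraction axis (total Na fixed),
#: at every setting of the other two dials.
MONOTONICITY_GRID = {
    "gh": (0.8, 1.6, 3.2),            # nS
    "gsk": (8.0, 12.0, 16.0),         # nS
    "na_fraction": (0.5, 0.65, 0.8),  # somatic share of total Na
    "total_na": 4500.0,               # nS
}


def grid_params(gh: float, gsk: float, na_fraction: float,
                base: NeuronParams | None = None) -> NeuronParams:
    """One cell of the monotonicity grid."""
    base = base or NeuronParams()
    total = MONOTONICITY_GRID["total_na"]
    return base.with_(gh=gh, gsk=gsk, gna_soma=total * na_fraction,
                      gna_ais=total * (1.0 - na_fraction))


def control_template() -> NeuronParams:
    """Default control-group template (the package's study conditions)."""
    return NeuronParams()


def shifted_template() -> NeuronParams:
    """Template with the two-hit-direction parameter shifts relative to
    control: lower leak conductance (higher input resistance), more
    negative leak reversal (hyperpolarized RMP), higher SK conductance
    (larger mAHP), and a higher somatic share of the sodium conductance
    (larger SD slope ratio), total sodium conductance unchanged."""
    ctrl = control_template()
    total_na = ctrl.gna_soma + ctrl.gna_ais
    frac = 0.88
    return ctrl.with_(
        leak_conductance=3.7,
        leak_reversal=-73.0,
        gsk=16.0,
        gna_soma=total_na * frac,
        gna_ais=total_na * (1.0 - frac),
    )


_JITTER_MULT = (
    "leak_conductance", "capacitance_soma", "capacitance_ais",
    "axial_conductance", "gna_soma", "gna_ais", "gk_dr", "gsk",
    "ca_tau", "gh", "gh_tau",
)
#: additive jitter scale for the leak reversal, mV per unit variability
REVERSAL_JITTER_MV = 10.0


def jitter_params(
    template: NeuronParams, variability: float, rng: np.random.Generator
) -> tuple[NeuronParams, list[str]]:
    """Draw one cell's parameters around a group template.

    Positive-scale parameters are jittered multiplicatively by
    ``1 + variability * N(0,1)`` (clipped at 0, clip events reported);
    the leak reversal is jittered additively with sd
    ``variability * 10 mV``.
    """
    if variability < 0:
        raise ValueError("inter-cell variability must be >= 0")
    updates = {}
    clipped = []
    for name in _JITTER_MULT:
        base = getattr(template, name)
        val = base * (1.0 + variability * rng.standard_normal())
        if val < 0:
            clipped.append(name)
            val = 0.0
        if name in ("capacitance_soma", "capacitance_ais", "ca_tau", "gh_tau"):
            val = max(val, 1e-3 * base) if base > 0 else val
        updates[name] = val
    updates["leak_reversal"] = (
        template.leak_reversal + variability * REVERSAL_JITTER_MV
        * rng.standard_normal()
    )
    cell = template.with_(**updates)
    return cell, clipped


def simulate_cohort(
    control_params: NeuronParams,
    shifted_params: NeuronParams,
    n_per_group: int,
    inter_cell_variability: float = 0.1,
    seed: int = 0,
    protocol: ProtocolSpec | None = None,
    substeps: int = 4,
    labels: tuple[str, str] = ("control", "shifted"),
) -> tuple[list[CellRecording], list[CellRecording], CohortGroundTruth]:
    """Simulate a two-group cohort by jittering each group's template.

    Each cell's parameters are reproducible draws from ``seed``; group
    labels are attached to the recordings.  Returns the two recording
    lists and the per-cell ground-truth parameter sets.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if protocol is None:
        protocol = ProtocolSpec.default_ladder()
    rng = np.random.default_rng(seed)
    groups: list[list[CellRecording]] = []
    per_cell = []
    clipped_all = []
    for gi, (template, label) in enumerate(
        zip((control_params, shifted_params), labels)
    ):
        recs = []
        for ci in range(n_per_group):
            cell_params, clipped = jitter_params(
                template, inter_cell_variability, rng
            )
            if clipped:
                clipped_all.append((label, ci, clipped))
            cell_seed = (int(seed) * 1009 + gi * 5003 + ci * 13) % (2**31 - 1)
            rec, truth = simulate_cell(
                cell_params, protocol, seed=cell_seed, substeps=substeps,
                cell_id=f"{label}_{ci:03d}", group=label,
            )
            recs.append(rec)
            per_cell.append((label, ci, truth))
        groups.append(recs)
    gt = CohortGroundTruth(per_cell_params=per_cell, seed=int(seed),
                           clipped_fields=clipped_all)
    return groups[0], groups[1], gt
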
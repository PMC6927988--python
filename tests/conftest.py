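"""Shared fixtures: simulated recordings are expensive, so the default
cell (full ladder) is simulated once per session and reused."""

import numpy as np
import pytest

from spikephase import (
    NeuronParams,
    ProtocolSpec,
    simulate_cell,
    two_sigmoid_spike,
)


@pytest.fixture(scope="session")
def default_cell():
    """Default excitable cell through the full 50->1500 pA ladder."""
    rec, gt = simulate_cell(NeuronParams(), ProtocolSpec.default_ladder(),
                            seed=7)
    return rec, gt


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced ladder covering rheobase and the 7-AP train."""
    return ProtocolSpec.default_ladder(start=100.0, stop=500.0, increment=50.0)


@pytest.fixture(scope="session")
def passive_params():
    """All active conductances zero: the analytic RC limit."""
    return NeuronParams(
        leak_conductance=10.0, leak_reversal=-65.0,
        gna_soma=0.0, gna_ais=0.0, gk_dr=0.0, gsk=0.0, gh=0.0,
    )


@pytest.fixture(scope="session")
def sigmoid_spike():
    """Biphasic analytic upstroke with solved reference values."""
    return two_sigmoid_spike()


def make_sweep_from_arrays(voltage, sampling_rate=50_000.0, current=None,
                           step_amplitude=0.0, step_onset=0.0,
                           step_offset=None):
    """Convenience constructor for hand-built trace fixtures."""
    from spikephase import Sweep

    voltage = np.asarray(voltage, dtype=float)
    if current is None:
        current = np.zeros_like(voltage)
    if step_offset is None:
        step_offset = voltage.size * 1000.0 / sampling_rate
    return Sweep(voltage=voltage, current=current,
                 sampling_rate=sampling_rate, step_amplitude=step_amplitude,
                 step_onset=step_onset, step_offset=step_offset)
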